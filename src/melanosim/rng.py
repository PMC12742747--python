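"""Reproducible per-individual, per-channel random substreams.

Each simulated individual gets an independent substream per event channel,
keyed by ``(root_seed, individual_id, channel)``.  Results are therefore
invariant to the order in which individuals are simulated, and the
natural-history channels (other-cause death, tumour emergence, histology,
body site, attribute assignment) consume draws in a fixed order that does
not depend on the screening policy.  This is what makes common-random-number
comparison of policies - and the paired counterfactual that the
overdiagnosis estimator needs - possible.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = ["Channel", "RandomStream", "NATURAL_HISTORY_CHANNELS"]


class Channel(IntEnum):
    ATTRIBUTES = 0        # sex, birth year, risk group
    OTHER_DEATH = 1
    EMERGENCE = 2         # one exponential deviate per tumour index
    HISTOLOGY = 3
    BODY_SITE = 4
    MELANOMA_DEATH = 5
    UPTAKE = 6
    VISIT = 7
    ROUTINE_CHECK = 8
    SCREEN = 9
    SURVEILLANCE = 10


#: Channels whose draws must not depend on the screening policy.
NATURAL_HISTORY_CHANNELS = frozenset(
    {Channel.ATTRIBUTES, Channel.OTHER_DEATH, Channel.EMERGENCE,
     Channel.HISTOLOGY, Channel.BODY_SITE}
)


class RandomStream:
    """Factory of per-(individual, channel) generators under one root seed."""

    def __init__(self, root_seed: int, individual_id: int = 0):
        self.root_seed = int(root_seed)
        self.individual_id = int(individual_id)
        self._generators: dict = {}

    def for_individual(self, individual_id: int) -> "RandomStream":
        return RandomStream(self.root_seed, individual_id)

    def channel(self, channel: Channel) -> np.random.Generator:
        """The generator for one channel of this individual (cached, so
        sequential draws within a channel advance its state)."""
        gen = self._generators.get(channel)
        if gen is None:
            ss = np.random.SeedSequence(
                entropy=(self.root_seed, self.individual_id, int(channel))
            )
            gen = np.random.Generator(np.random.PCG64(ss))
            self._generators[channel] = gen
        return gen
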