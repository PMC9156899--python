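"""Named seed substreams.

All randomness in the package flows from a single master seed; independent
stages (design shuffling, cohort simulation, optimizer restarts,
down-sampling) draw from named substreams so that changing one stage's
consumption never perturbs another's.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "substream"]


def substream_seed(master: int, *names) -> int:
    """Deterministic child seed (< 2**31) for a named substream."""
    tag = "/".join(str(n) for n in names)
    return int(np.random.SeedSequence([int(master), zlib.crc32(tag.encode())]).generate_state(1)[0] % (2**31))


def substream(master: int, *names) -> np.random.Generator:
    """Generator for a named substream of the master seed."""
    return np.random.default_rng(substream_seed(master, *names))
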