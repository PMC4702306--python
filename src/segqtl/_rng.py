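"""Named, reproducible random substreams.

All stochastic stages (marker placement, meiosis, mating, phenotype noise,
sequencing) draw from independent generators derived from a single root seed,
so any one stage can be re-run bit-for-bit without replaying the others.
"""

from __future__ import annotations

import numpy as np

#: fixed ids so stream identity never depends on call order
_STREAMS = {
    "markers": 11,
    "meiosis": 23,
    "mating": 37,
    "phenotype": 53,
    "sequencing": 71,
    "selection": 89,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the generator for the named stage under a root seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown random substream {name!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)


def as_rng(seed_or_rng: "int | np.random.Generator", name: str = "meiosis") -> np.random.Generator:
    """Accept either a root seed or an already-built generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return substream(int(seed_or_rng), name)
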