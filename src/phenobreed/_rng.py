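"""Named random substreams derived from one master seed.

Every stochastic step in the package draws from its own substream, keyed by a
stable string path (e.g. ``("IA-RS", "residual")``).  Substreams are mutually
independent, so changing the draw count of one step (or skipping it entirely)
never perturbs another step's values — e.g. raising the missingness rate does
not alter the yields that were generated.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_int"]


def _key_ints(keys) -> list[int]:
    return [zlib.crc32(str(k).encode("utf-8")) for k in keys]


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return an independent ``numpy`` Generator for the named substream."""
    ss = np.random.SeedSequence([int(master_seed), *_key_ints(keys)])
    return np.random.default_rng(ss)


def child_int(master_seed: int, *keys) -> int:
    """A 31-bit integer seed for libraries that accept plain int seeds."""
    ss = np.random.SeedSequence([int(master_seed), *_key_ints(keys)])
    return int(ss.generate_state(1)[0] % (2**31))
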