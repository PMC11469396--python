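"""Named, reproducible random streams.

Every stochastic step in the pipeline draws from its own named stream so that
(a) the same master seed yields bit-identical results for the whole pipeline,
and (b) adding draws to one step never perturbs another step's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["RNGHandle"]


class RNGHandle:
    """Factory of independent ``numpy.random.Generator`` streams.

    Parameters
    ----------
    seed : int
        Master seed. Two handles with the same seed produce bit-identical
        streams for every label, regardless of the order streams are asked for.
    """

    def __init__(self, seed: int):
        if not isinstance(seed, (int, np.integer)):
            raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
        self.seed = int(seed)

    def stream(self, label: str) -> np.random.Generator:
        """Return a fresh generator for ``label``, deterministic in (seed, label)."""
        # crc32 gives a stable 32-bit hash (python's hash() is salted per process)
        key = zlib.crc32(label.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RNGHandle(seed={self.seed})"
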