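"""Named random substreams.

One global seed feeds every stage of the pipeline; each stage pulls its own
independent generator keyed by a stage name, so a stage rerun in isolation
reproduces the values it produced inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator deterministically derived from ``seed`` and names.

    The derivation is a SeedSequence keyed on the CRC32 of each name, so it is
    stable across processes and platforms.
    """
    keys = [zlib.crc32(n.encode("utf-8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))
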