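"""Named, reproducible random substreams.

Every stochastic operation in the package derives its generator from one
top-level integer seed plus a string path naming the operation (and, where
relevant, the subject / run / iteration). This keeps the whole pipeline
reproducible from a single seed while decoupling the streams: changing how
many draws one stage makes never perturbs another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _name_to_words(name: str) -> list[int]:
    data = name.encode("utf-8")
    # crc32 of successive prefixes gives a stable, order-sensitive word list
    return [zlib.crc32(data), zlib.crc32(data[::-1]), len(data)]


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    Parameters
    ----------
    seed : int
        Top-level seed (non-negative, < 2**31).
    *names : str or int
        Path components, e.g. ``("design", context, phase)`` or
        ``("perm", subject_id, iteration)``.
    """
    entropy: list[int] = [int(seed) & 0x7FFFFFFF]
    for part in names:
        if isinstance(part, (int, np.integer)):
            entropy.append(int(part) & 0xFFFFFFFF)
        else:
            entropy.extend(_name_to_words(str(part)))
    return np.random.default_rng(np.random.SeedSequence(entropy))
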