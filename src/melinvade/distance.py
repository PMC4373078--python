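"""Gower-type mixed-data distances with pairwise deletion of missing scores."""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .characters import CharacterDefinition

log = logging.getLogger(__name__)

RangeMode = Literal["observed", "theoretical"]


def mixed_distance(scores: pd.DataFrame,
                   range_mode: RangeMode = "observed",
                   definitions: Sequence[CharacterDefinition] | None = None,
                   ) -> pd.DataFrame:
    """Gower distance between specimens over ordinal characters.

    Per character the contribution is |x - y| / range; contributions are
    averaged over the characters where both specimens are scored.  Ranges are
    either the observed column range (max - min over non-missing entries) or
    the theoretical span of the character's allowed states.

    Raises ValueError if two specimens share no jointly scored character.
    Zero-range characters (observed mode) carry no information and are
    dropped with a warning.
    """
    values = scores.to_numpy(dtype=float)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least 2 specimens")

    if range_mode == "theoretical":
        if definitions is None:
            raise ValueError("theoretical ranges require character definitions")
        by_code = {d.code: d for d in definitions}
        ranges = np.array([float(by_code[c].span) for c in scores.columns])
    elif range_mode == "observed":
        with np.errstate(all="ignore"):
            ranges = np.nanmax(values, axis=0) - np.nanmin(values, axis=0)
        ranges = np.where(np.isnan(ranges), 0.0, ranges)
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")

    zero = ranges <= 0
    if zero.any():
        log.warning("dropping zero-range character(s) from distances: %s",
                    list(scores.columns[zero]))
    keep = ~zero
    v = values[:, keep]
    r = ranges[keep]
    observed = ~np.isnan(v)

    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = observed[i] & observed[j]
            if not both.any():
                raise ValueError(
                    f"specimens {scores.index[i]!r} and {scores.index[j]!r} "
                    f"share no jointly scored character")
            contrib = np.abs(v[i, both] - v[j, both]) / r[both]
            d[i, j] = d[j, i] = contrib.mean()
    return pd.DataFrame(d, index=scores.index, columns=scores.index)


def euclidean_distance(scores: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance with pairwise deletion of missing scores.

    Missing characters are dropped per pair and the squared-difference sum is
    rescaled by p / p_shared (the convention of R's dist()), so pairs judged
    on fewer characters are not systematically closer.
    """
    values = scores.to_numpy(dtype=float)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least 2 specimens")
    observed = ~np.isnan(values)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = observed[i] & observed[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"specimens {scores.index[i]!r} and {scores.index[j]!r} "
                    f"share no jointly scored character")
            ss = float(np.sum((values[i, both] - values[j, both]) ** 2))
            d[i, j] = d[j, i] = np.sqrt(ss * p / m)
    return pd.DataFrame(d, index=scores.index, columns=scores.index)
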