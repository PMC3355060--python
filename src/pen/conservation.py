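"""Entropy-based conservation index (EC) over MSSA columns.

Each alignment column gets a raw score c = sum_a p_a ln p_a (the negative of
the Shannon entropy of its amino-acid frequencies, natural log, gaps excluded
from the counts): a fully conserved column scores 0 and a maximally diverse
one approaches -ln 20.  Raw scores are then z-normalized across the defined
columns of the alignment, so EC > 0 marks columns more conserved than the
alignment average and EC < 0 less conserved.  The population (ddof = 0)
standard deviation is the default normalizer.  Sequences are counted
unweighted; families are assumed pre-culled of redundant members.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .family import GAP_CHARS, MSSA


@dataclass
class ECProfile:
    """Per-column raw conservation and z-normalized EC.

    All-gap columns are undefined: NaN in both arrays, excluded from the
    normalization.
    """

    raw: np.ndarray
    ec: np.ndarray
    n_non_gap: np.ndarray

    @property
    def L(self) -> int:
        return self.raw.shape[0]


def column_conservation(mssa: MSSA, column: int) -> float:
    """Raw conservation sum_a p_a ln p_a of one column (0-based), gaps excluded.

    Raises for an all-gap column, which has no defined composition.
    """
    symbols = [
        mssa.sequences[m][column]
        for m in mssa.member_ids
        if mssa.sequences[m][column] not in GAP_CHARS
    ]
    if not symbols:
        raise ValueError(f"column {column} is all-gap; conservation undefined")
    counts = np.array(list(Counter(symbols).values()), dtype=float)
    p = counts / counts.sum()
    return float(np.sum(p * np.log(p)))


def ec_scores(mssa: MSSA, ddof: int = 0) -> ECProfile:
    """Raw conservation per column, z-normalized into EC across defined columns.

    ``ddof`` selects the population (0, default) or sample (1) standard
    deviation.  If every defined column has identical raw conservation the
    spread is zero and all EC values are set to 0 with a warning.
    """
    L = mssa.L
    raw = np.full(L, np.nan)
    n_non_gap = np.zeros(L, dtype=int)
    for c in range(L):
        n = sum(
            1 for m in mssa.member_ids if mssa.sequences[m][c] not in GAP_CHARS
        )
        n_non_gap[c] = n
        if n > 0:
            raw[c] = column_conservation(mssa, c)
    defined = ~np.isnan(raw)
    if defined.sum() < 2:
        raise ValueError("need at least two defined columns to normalize")
    mean = raw[defined].mean()
    sd = raw[defined].std(ddof=ddof)
    ec = np.full(L, np.nan)
    if sd == 0:
        warnings.warn(
            "all defined columns share one conservation value; EC set to 0",
            stacklevel=2,
        )
        ec[defined] = 0.0
    else:
        ec[defined] = (raw[defined] - mean) / sd
    return ECProfile(raw=raw, ec=ec, n_non_gap=n_non_gap)
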