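"""Land-cover class proportions and epoch-to-epoch transition matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def class_proportions(landcover: np.ndarray, class_names: tuple | list
                      ) -> dict[str, float]:
    """Percent of valid pixels per class (sums to 100).

    ``landcover`` holds integer codes into ``class_names``; negative codes
    count as nodata.
    """
    lc = np.asarray(landcover)
    valid = lc >= 0
    n = int(valid.sum())
    if n == 0:
        raise ValueError("empty land-cover grid")
    out = {}
    for code, name in enumerate(class_names):
        out[name] = 100.0 * int((lc[valid] == code).sum()) / n
    return out


@dataclass
class TransitionMatrix:
    """From x to cross-tabulation between two epochs."""

    counts: pd.DataFrame          # rows = epoch-1 class, cols = epoch-2 class
    proportions: pd.DataFrame     # counts / total, in percent
    n_valid: int

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def transition_matrix(lc_t1: np.ndarray, lc_t2: np.ndarray,
                      class_names: tuple | list) -> TransitionMatrix:
    """Cross-tabulate classes between two co-registered categorical rasters.

    Pixels nodata (negative code) in either epoch are excluded.  Codes
    outside the class vocabulary raise with the offending labels listed.
    """
    a = np.asarray(lc_t1)
    b = np.asarray(lc_t2)
    if a.shape != b.shape:
        raise ValueError("epoch grids must be co-registered")
    valid = (a >= 0) & (b >= 0)
    av, bv = a[valid].ravel(), b[valid].ravel()
    n_classes = len(class_names)
    bad = np.unique(np.concatenate([av[av >= n_classes], bv[bv >= n_classes]]))
    if bad.size:
        raise ValueError(f"unknown class codes: {bad.tolist()}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (av, bv), 1)
    counts_df = pd.DataFrame(counts, index=list(class_names),
                             columns=list(class_names))
    total = int(valid.sum())
    props = 100.0 * counts_df / total if total else counts_df * np.nan
    return TransitionMatrix(counts_df, props, total)
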