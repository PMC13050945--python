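"""Inter-rater reliability via Krippendorff's alpha.

Raters assign label *sets*, so agreement is assessed one discourse at a
time: for each of the five discourses, a reliability matrix of binary
presence/absence codings (raters x sentences) is built and nominal-metric
alpha = 1 - D_o/D_e is computed with the standard coincidence-matrix
bookkeeping, which handles missing cells (a rater who cast no votes at all
on a sentence).  The report covers all raters together and every rater
pair.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import DISCOURSE_CODES, RaterVotes, Sentence, ValidationError

__all__ = [
    "UndefinedAgreementError",
    "reliability_matrix",
    "krippendorff_alpha",
    "agreement_report",
]


class UndefinedAgreementError(ValueError):
    """No pairable values: alpha is undefined."""


def reliability_matrix(
    raw_votes: Sequence[tuple[Sentence, Sequence[RaterVotes]]],
    discourse: str,
    raters: Sequence[int] | None = None,
) -> np.ndarray:
    """Binary presence matrix (raters x sentences) for one discourse.

    A cell is 1 if the rater's vote set contains the discourse, 0 if it
    does not, and NaN (missing) if the rater cast no votes on the sentence.
    ``raters`` selects rater slots by index (default: all).
    """
    n_raters = len(raw_votes[0][1])
    idx = list(raters) if raters is not None else list(range(n_raters))
    mat = np.full((len(idx), len(raw_votes)), np.nan)
    for j, (_, per_rater) in enumerate(raw_votes):
        for i, r in enumerate(idx):
            rv = per_rater[r]
            if rv.discourse_votes:
                mat[i, j] = float(discourse in rv.discourse_labels)
            # a rater with no discourse votes at all is a missing cell
    return mat


def krippendorff_alpha(matrix: np.ndarray) -> float:
    """Nominal-metric Krippendorff alpha for a (raters x units) matrix.

    Cells are category codes (here 0/1) with NaN for missing.  Units with
    fewer than two non-missing cells are ignored.  Perfect agreement gives
    1; chance-level agreement concentrates near 0; zero expected
    disagreement (only one category ever used) is treated as perfect
    agreement.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValidationError("matrix must be (>=2 raters) x (>=1 units)")
    values = np.unique(matrix[~np.isnan(matrix)])
    if values.size == 0:
        raise UndefinedAgreementError("no ratings at all")
    index = {v: i for i, v in enumerate(values)}
    k = len(values)
    coincidence = np.zeros((k, k))
    any_pairable = False
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        col = col[~np.isnan(col)]
        m = col.size
        if m < 2:
            continue
        any_pairable = True
        for a in col:
            for b in col:
                coincidence[index[a], index[b]] += 1.0 / (m - 1)
        for a in col:  # remove self-pairs
            coincidence[index[a], index[a]] -= 1.0 / (m - 1)
    if not any_pairable:
        raise UndefinedAgreementError("no unit has two or more ratings")
    n_c = coincidence.sum(axis=1)
    n = n_c.sum()
    observed = coincidence.sum() - np.trace(coincidence)
    expected = (np.outer(n_c, n_c).sum() - (n_c**2).sum()) / (n - 1)
    if expected == 0.0:
        return 1.0  # a single category in use: no disagreement is possible
    return float(1.0 - observed / expected)


def agreement_report(
    raw_votes: Sequence[tuple[Sentence, Sequence[RaterVotes]]],
) -> pd.DataFrame:
    """Per-discourse alpha for all raters together and for every rater pair.

    Returns a DataFrame with columns ``discourse``, ``raters`` (e.g. ``all``
    or ``1-2``) and ``alpha``; 5 discourses x (1 + pairs) rows.  An
    undefined alpha (no pairable values) is reported as NaN.
    """
    if not raw_votes:
        raise ValidationError("no votes")
    n_raters = len(raw_votes[0][1])
    groups: list[tuple[str, list[int]]] = [("all", list(range(n_raters)))]
    groups += [
        (f"{a + 1}-{b + 1}", [a, b]) for a, b in combinations(range(n_raters), 2)
    ]
    rows = []
    for discourse in DISCOURSE_CODES:
        for name, idx in groups:
            mat = reliability_matrix(raw_votes, discourse, idx)
            try:
                alpha = krippendorff_alpha(mat)
            except UndefinedAgreementError:
                alpha = float("nan")
            rows.append({"discourse": discourse, "raters": name, "alpha": alpha})
    return pd.DataFrame(rows, columns=["discourse", "raters", "alpha"])
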