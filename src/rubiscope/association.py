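"""Alignment-position association with carboxylation rate.

The procedure resamples shallow regression trees: the one-hot encoded
alignment is split 100 times into 75% training / 25% held-out rows, a
depth-3 regression tree (variance-reduction splits) is fitted on each
training set, and exact Shapley values are computed for every held-out
row.  Mean absolute attributions are summed over the residue states of
each alignment position (the states are mutually exclusive indicators)
and averaged across iterations, yielding one association score per
position in ln-rate units.  Positions are reported in the numbering of
a reference sequence (the R. rubrum enzyme in the rubisco analyses).

A separate helper compares rates between residue groups at a single
position with a tie-corrected Kruskal-Wallis omnibus test followed by
Dunn pairwise comparisons (Bonferroni-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .predict import EncodedMatrix
from .seqspace import GAP, AlignedSeqSet
from .shapley import TreeExplainer


@dataclass
class AssociationConfig:
    """Resampling scheme for the position-association analysis."""

    n_iterations: int = 100
    train_fraction: float = 0.75
    max_depth: int = 3
    seed: int = 0
    forms: tuple[str, ...] | None = None  # e.g. ("II", "II/III")

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class PositionAssociation:
    """Mean absolute Shapley attribution per alignment position."""

    scores: np.ndarray  # per alignment position, ln-rate units
    reference_map: dict[int, int] | None = None  # column -> reference residue no.
    config: AssociationConfig | None = None

    def ranked(self) -> pd.DataFrame:
        order = np.argsort(-self.scores)
        rows = []
        for rank, col in enumerate(order, start=1):
            ref = self.reference_map.get(int(col)) if self.reference_map else None
            rows.append((int(col), ref, float(self.scores[col]), rank))
        return pd.DataFrame(rows, columns=["column", "ref_residue", "score", "rank"])

    def rank_of_column(self, column: int) -> int:
        order = np.argsort(-self.scores)
        return int(np.flatnonzero(order == column)[0]) + 1

    def top_column(self) -> int:
        return int(np.argmax(self.scores))


def fit_position_association(
    enc: EncodedMatrix,
    y: Sequence[float],
    cfg: AssociationConfig | None = None,
    reference_map: dict[int, int] | None = None,
) -> PositionAssociation:
    """Resampled tree regression + exact Shapley, aggregated per position.

    Iteration i draws a seeded 75/25 split (seed = master seed + i),
    fits a depth-limited tree on the training rows and attributes every
    held-out row's prediction to the one-hot features with exact tree
    Shapley values.  Per feature the mean absolute attribution over
    held-out rows is taken; per position the feature values of its
    residue states are summed; the final score is the mean over
    iterations.  Fully deterministic for a fixed master seed.
    """
    cfg = cfg or AssociationConfig()
    X = np.asarray(enc.X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < 20:
        raise ValueError("need at least 20 rows for a stable resampling analysis")
    if not np.isfinite(y).all():
        raise ValueError("y must be finite")
    positions = enc.positions()
    n_train = max(1, int(round(cfg.train_fraction * n)))
    if n_train >= n:
        n_train = n - 1
    scores = np.zeros(p)
    for it in range(cfg.n_iterations):
        rng = np.random.default_rng(cfg.seed + it)
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        tree = DecisionTreeRegressor(
            max_depth=cfg.max_depth,
            criterion="squared_error",
            random_state=int(cfg.seed + it),
        )
        tree.fit(X[train], y[train])
        explainer = TreeExplainer(tree)
        shap, _ = explainer.shap_matrix(X[test])
        scores += np.abs(shap).mean(axis=0)
    scores /= cfg.n_iterations
    per_position = np.zeros(enc.n_positions)
    np.add.at(per_position, positions, scores)
    return PositionAssociation(
        scores=per_position, reference_map=reference_map, config=cfg
    )


# ---------------------------------------------------------------------------
# Reference numbering
# ---------------------------------------------------------------------------

def map_alignment_to_reference(aln: AlignedSeqSet, ref_id: str) -> dict[int, int]:
    """Map alignment columns to 1-based residue numbers of a reference row.

    Columns where the reference carries a gap are absent from the map;
    the map is strictly increasing over the mapped columns.
    """
    row = aln.rows[aln.index_of(ref_id)]
    out: dict[int, int] = {}
    residue = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            residue += 1
            out[col] = residue
    return out


def column_for_reference_residue(
    aln: AlignedSeqSet, ref_id: str, residue_number: int
) -> int:
    """Alignment column holding the reference's residue ``residue_number``."""
    for col, num in map_alignment_to_reference(aln, ref_id).items():
        if num == residue_number:
            return col
    raise ValueError(
        f"reference {ref_id!r} has no residue number {residue_number}"
    )


# ---------------------------------------------------------------------------
# Residue-group rate comparison
# ---------------------------------------------------------------------------

@dataclass
class ResidueRateComparison:
    """Kruskal-Wallis omnibus plus Dunn pairwise z tests for rate-by-residue."""

    groups: dict[str, np.ndarray]
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.groups.values())


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H; degenerate all-equal data gives H=0."""
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_test(
    groups: Mapping[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's post-hoc rank comparisons with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; two-sided normal p-values,
    Bonferroni-adjusted across the comparisons.
    """
    labels = list(groups)
    sizes = {g: len(groups[g]) for g in labels}
    flat = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(flat)
    n_total = len(flat)
    mean_ranks = {}
    start = 0
    for g in labels:
        mean_ranks[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, counts = np.unique(flat, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    rows = []
    pairs = list(combinations(labels, 2))
    for a, b in pairs:
        denom = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if denom == 0 else (mean_ranks[a] - mean_ranks[b]) / denom
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p_raw)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p_raw"] * len(pairs), 1.0)
    elif adjust == "none":
        df["p_adjusted"] = df["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def residue_rate_comparison(
    aln: AlignedSeqSet,
    column: int,
    rates: Mapping[str, float],
    grouping: Mapping[str, str] | None = None,
    min_group_size: int = 1,
) -> ResidueRateComparison:
    """Compare rates between residue groups at one alignment column.

    ``grouping`` optionally merges residues into classes (e.g. mapping
    I, V and H to a single "I/V/H" group); ungrouped residues form their
    own singleton classes.  Variants without a rate or with a gap at the
    column are ignored.  Requires at least two non-empty groups.
    """
    buckets: dict[str, list[float]] = {}
    for sid, row in zip(aln.ids, aln.rows):
        if sid not in rates:
            continue
        ch = row[column]
        if ch == GAP:
            continue
        label = grouping.get(ch, ch) if grouping else ch
        buckets.setdefault(label, []).append(float(rates[sid]))
    groups = {
        g: np.asarray(v, float)
        for g, v in buckets.items()
        if len(v) >= min_group_size
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty residue groups")
    h, p = kruskal_wallis(list(groups.values()))
    pairwise = dunn_test(groups)
    return ResidueRateComparison(
        groups=groups, h_statistic=h, p_value=p, pairwise=pairwise
    )
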