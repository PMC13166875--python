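"""Length-normalized hypergeometric enrichment of positive selection.

The unit of observation is a gene-tree branch carrying a p-value from an
upstream branch-site test for positive selection. Long branches are more
likely to harbor a detectable selection event than short ones, so raw branch
counts are biased; each branch instead contributes a weight equal to its
length divided by the mean branch length of its dataset, and the rounded
weight totals serve as the population size (all tested branches) and the
draw size (branches mapped onto the transition species branches) of a
hypergeometric test. Significant branches (p below the call threshold,
default 0.05) are counted as unweighted events.

Convergent trait changes are pooled: tallies for all species branches
showing the same change, across all clade × subfamily datasets, are summed
before a single test. Both one-sided p-values (enrichment and depletion) are
computed and the one matching the observed direction of the fold is
reported; Benjamini–Hochberg correction is applied across the family of
reported tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import (DegenerateLengthsError, DoubleCountError,
                     EmptyPopulationError, UnknownBranchError)

__all__ = ["BranchTestRecord", "TransitionSet", "ContingencyTally",
           "EnrichmentResult", "normalize_weights", "tally", "hypergeom_test",
           "pool", "bh_correct", "enrichment_analysis", "records_from_frame"]

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["dataset_id", "gene_tree_id", "gene_branch_id",
                  "branch_length", "p_value"]


@dataclass(frozen=True)
class BranchTestRecord:
    """One gene-tree branch with its length and selection-test p-value."""

    dataset_id: str
    gene_tree_id: str
    gene_branch_id: int
    branch_length: float
    p_value: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.branch_length < 0:
            raise ValueError(f"negative branch length {self.branch_length}")


@dataclass
class TransitionSet:
    """Species-tree branches sharing one inferred trait change (pooling unit).

    ``members`` holds ``(dataset_id, species_branch_id)`` pairs.
    """

    label: str
    members: list[tuple[str, object]] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"transition set {self.label!r} has no members")


@dataclass
class ContingencyTally:
    """Length-normalized hypergeometric contingency quantities.

    N_w: rounded weighted population size; K: significant branches in the
    population; n_w: rounded weighted draw size on transition branches;
    k: significant branches on transition branches.
    """

    N_w: int
    K: int
    n_w: int
    k: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.K, self.n_w) and
                self.n_w <= self.N_w and self.K <= self.N_w):
            raise ValueError(f"inconsistent tally {self}")


@dataclass
class EnrichmentResult:
    tally: ContingencyTally
    expected: float
    fold: float
    p_enrich: float
    p_deplete: float
    p_reported: float
    direction: str
    label: str | None = None
    q_value: float | None = None


def records_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a branch-test table and return it with canonical columns."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"branch test table missing columns: {missing}")
    out = df[RECORD_COLUMNS].copy()
    if ((out["p_value"] < 0) | (out["p_value"] > 1)).any():
        raise ValueError("p_value outside [0, 1]")
    if (out["branch_length"] < 0).any():
        raise ValueError("negative branch lengths")
    key = out[["dataset_id", "gene_tree_id", "gene_branch_id"]]
    if key.duplicated().any():
        raise ValueError("duplicate (dataset, tree, branch) records")
    return out


def normalize_weights(records: pd.DataFrame, strict: bool = True) -> np.ndarray:
    """Per-record weight: branch length over the dataset-mean branch length.

    Weights sum to the record count within every dataset. A dataset whose
    branch lengths are all zero has no defined normalization: with
    ``strict=True`` this raises :class:`DegenerateLengthsError`; otherwise
    unit weights are used for that dataset and a warning is logged.
    """
    lengths = records["branch_length"].to_numpy(float)
    weights = np.empty_like(lengths)
    for ds, idx in records.groupby("dataset_id", sort=False).indices.items():
        mean = lengths[idx].mean()
        if mean <= 0:
            if strict:
                raise DegenerateLengthsError(f"dataset {ds!r} has all-zero branch lengths")
            log.warning("dataset %r has all-zero branch lengths; using unit weights", ds)
            weights[idx] = 1.0
        else:
            weights[idx] = lengths[idx] / mean
    return weights


def _round_half_even(x: float) -> int:
    return int(np.round(x))


def tally(records: pd.DataFrame, weights: np.ndarray,
          assignment: pd.Series | np.ndarray,
          transition: TransitionSet, alpha: float = 0.05,
          known_branches: set | None = None,
          weighted_successes: bool = False) -> ContingencyTally:
    """Build the contingency tally for one transition set.

    Parameters
    ----------
    assignment
        Species branch id per record (aligned with *records*), from
        reconciliation.
    alpha
        Per-branch significance call threshold on the upstream test p-value.
    known_branches
        Optional set of ``(dataset_id, species_branch_id)`` pairs that exist
        in the species trees; transition members outside it raise
        :class:`UnknownBranchError`.

    Weighted sizes are rounded half-to-even and clamped so the tally
    invariants survive rounding; significant-branch counts stay unweighted
    events unless ``weighted_successes`` is set, in which case K and k are
    rounded weight sums too (the alternative reading of the normalization,
    off by default).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    assignment = np.asarray(assignment, dtype=object)
    if known_branches is not None:
        bad = [m for m in transition.members if m not in known_branches]
        if bad:
            raise UnknownBranchError(f"transition members not in assignment universe: {bad}")
    members = set(transition.members)
    ds = records["dataset_id"].to_numpy(object)
    on = np.fromiter(((d, b) in members for d, b in zip(ds, assignment)),
                     dtype=bool, count=len(ds))
    sig = records["p_value"].to_numpy(float) < alpha
    N_w = _round_half_even(float(weights.sum()))
    n_w = _round_half_even(float(weights[on].sum()))
    if weighted_successes:
        K = _round_half_even(float(weights[sig].sum()))
        k = _round_half_even(float(weights[sig & on].sum()))
    else:
        K = int(sig.sum())
        k = int((sig & on).sum())
    # rounding can push weighted sizes below the event counts; clamp upward
    N_w = max(N_w, K, n_w, 1 if len(records) else 0)
    n_w = min(max(n_w, k), N_w)
    return ContingencyTally(N_w=N_w, K=K, n_w=n_w, k=k)


def pool(tallies: list[ContingencyTally]) -> ContingencyTally:
    """Component-wise sum of tallies from disjoint datasets/branches."""
    if not tallies:
        raise DoubleCountError("nothing to pool")
    return ContingencyTally(
        N_w=sum(t.N_w for t in tallies), K=sum(t.K for t in tallies),
        n_w=sum(t.n_w for t in tallies), k=sum(t.k for t in tallies))


def hypergeom_test(t: ContingencyTally, label: str | None = None) -> EnrichmentResult:
    """Two one-sided hypergeometric tests; report the direction-matching one.

    ``p_enrich = P(X >= k)`` and ``p_deplete = P(X <= k)`` for
    ``X ~ Hypergeom(N_w, K, n_w)``. The observed/expected fold determines the
    direction (enrichment when fold >= 1) and hence the reported p-value.
    With an empty draw or no significant branches the expectation is 0 and
    the fold is undefined (NaN, flagged by direction ``"enrichment"`` with
    p = 1).
    """
    if t.N_w == 0:
        raise EmptyPopulationError("empty branch population (N_w = 0)")
    expected = t.n_w * t.K / t.N_w
    fold = t.k / expected if expected > 0 else float("nan")
    p_enrich = float(hypergeom.sf(t.k - 1, t.N_w, t.K, t.n_w))
    p_deplete = float(hypergeom.cdf(t.k, t.N_w, t.K, t.n_w))
    p_enrich = min(1.0, max(0.0, p_enrich))
    p_deplete = min(1.0, max(0.0, p_deplete))
    if np.isnan(fold) or fold >= 1.0:
        direction, p_reported = "enrichment", p_enrich
    else:
        direction, p_reported = "depletion", p_deplete
    return EnrichmentResult(tally=t, expected=expected, fold=fold,
                            p_enrich=p_enrich, p_deplete=p_deplete,
                            p_reported=p_reported, direction=direction,
                            label=label)


def bh_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrichment_analysis(records: pd.DataFrame,
                        assignment: pd.Series | np.ndarray,
                        transitions: list[TransitionSet],
                        alpha: float = 0.05,
                        strict_lengths: bool = True) -> pd.DataFrame:
    """Run the full tally → test → BH pipeline for a list of transition sets.

    Returns one row per transition label with the tally components, expected
    count, fold, both one-sided p-values, the reported p and its q-value.
    """
    records = records_from_frame(records)
    weights = normalize_weights(records, strict=strict_lengths)
    results = []
    for tr in transitions:
        t = tally(records, weights, assignment, tr, alpha=alpha)
        results.append(hypergeom_test(t, label=tr.label))
    q = bh_correct([r.p_reported for r in results])
    rows = []
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        rows.append({
            "label": r.label, "N_w": r.tally.N_w, "K": r.tally.K,
            "n_w": r.tally.n_w, "k": r.tally.k, "expected": r.expected,
            "fold": r.fold, "p_enrich": r.p_enrich, "p_deplete": r.p_deplete,
            "p_reported": r.p_reported, "direction": r.direction, "q": r.q_value,
        })
    return pd.DataFrame(rows)
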