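"""Differential alternative splicing over TSS groups.

For each TSS group (isoforms of one gene sharing a transcription start
site) the relative abundance of every member — its *isoform ratio*, the
member's share of the group's total FPKM — is computed per condition.  A
gene undergoes differential alternative splicing (dAS) between flight and
ground when the group's ratio vectors differ more than replicate noise
explains.  The test statistic is the square root of the Jensen–Shannon
divergence (log base 2, so the statistic lives in [0, 1] and is a metric)
between the two conditions' ratio vectors; significance comes from a
replicate-label permutation null, exhaustively enumerated when the number
of label assignments is small (C(8,4) = 70 for the default 4 + 4 design)
and Monte-Carlo sampled otherwise.  p-values are Benjamini–Hochberg
adjusted across all tested groups of a comparison pair.

Members whose ratio is below epsilon (default 0.01) in BOTH conditions are
removed before testing.  Reported ratio vectors are NOT renormalised after
this removal (so they stay comparable to raw per-condition shares); the
test statistic, however, is computed on the renormalised surviving members
so that its inputs are probability distributions.

A *dominant-isoform switch* is flagged when the highest-ratio member of
the group differs between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .quantification import Condition, ExpressionMatrix, condition_slice
from .transcriptome import TssGroup

DEFAULT_EPSILON = 0.01
DEFAULT_ALPHA = 0.05
EXHAUSTIVE_LIMIT = 10_000
RATIO_MODES = ("condition-mean", "per-replicate-mean")

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class IsoformRatioTable:
    """Per-member isoform ratios of one TSS group in one condition.

    ``defined`` is False when the group's total mean FPKM is zero, in which
    case ratios are meaningless and the group is excluded from testing
    (an all-or-nothing expression difference is a PAV phenomenon, handled
    by the pav module, not a splicing-ratio change).
    """

    group: TssGroup
    condition: Condition
    member_ids: tuple[str, ...]
    ratios: tuple[float, ...]
    defined: bool

    def as_series(self) -> pd.Series:
        return pd.Series(self.ratios, index=list(self.member_ids))


@dataclass
class DasResult:
    """Per TSS group outcome of the differential-splicing test."""

    gene_id: str
    tss_key: str
    member_ids: tuple[str, ...]
    ratios_flight: tuple[float, ...]  # unrenormalised post-filter shares
    ratios_ground: tuple[float, ...]
    jsd_sqrt: float
    p_value: float
    n_assignments: int
    exhaustive: bool
    q_value: float = float("nan")
    is_significant: bool = False
    switch: bool = False


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    p_value: float
    n_assignments: int
    exhaustive: bool


# --------------------------------------------------------------------------
# statistic
# --------------------------------------------------------------------------

def jsd_sqrt(p: Sequence[float], q: Sequence[float], *, base: float = 2.0) -> float:
    """Square-root Jensen–Shannon divergence between two ratio vectors.

    Inputs must be same-length (>= 2) non-negative vectors each summing to
    1 within 1e-9.  With log base 2 the divergence is bounded by 1, so the
    returned statistic is in [0, 1]; it is 0 iff p == q and is a metric on
    probability vectors.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if p.ndim != 1 or p.size < 2:
        raise ValueError("ratio vectors must be 1-d with at least 2 entries")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any():
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"{name} does not sum to 1 (got {v.sum()!r})")
    return float(_jsd_sqrt_columns(p[:, None], q[:, None], base=base)[0])


def _jsd_sqrt_columns(P: np.ndarray, Q: np.ndarray, *, base: float = 2.0) -> np.ndarray:
    """Column-wise sqrt-JSD for stacks of distributions (k x n arrays).

    Columns containing NaN propagate NaN.  0 * log 0 terms are 0 by
    continuity; mixture entries are positive wherever p or q is.
    """
    M = 0.5 * (P + Q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = np.where(P > 0, P * (np.log(P) - np.log(M)), 0.0)
        kl_q = np.where(Q > 0, Q * (np.log(Q) - np.log(M)), 0.0)
    nan_cols = np.isnan(P).any(axis=0) | np.isnan(Q).any(axis=0)
    jsd = 0.5 * (kl_p.sum(axis=0) + kl_q.sum(axis=0)) / np.log(base)
    # clip tiny negative rounding; bound by 1 for base 2
    jsd = np.clip(jsd, 0.0, None)
    out = np.sqrt(jsd)
    out[nan_cols] = np.nan
    return out


# --------------------------------------------------------------------------
# ratios
# --------------------------------------------------------------------------

def isoform_ratios(
    m: ExpressionMatrix,
    g: TssGroup,
    c: Condition,
    *,
    members: Sequence[str] | None = None,
    mode: str = "condition-mean",
) -> IsoformRatioTable:
    """Isoform ratios of a TSS group's members in one condition.

    ``mode="condition-mean"`` (default) divides each member's mean FPKM over
    the condition's replicates by the group total of those means.
    ``mode="per-replicate-mean"`` computes the ratio within each replicate
    and averages over replicates (replicates with zero group total are
    skipped).  ``members`` restricts the computation to a subset of the
    group (used after presence filtering); by default all members are used.
    """
    if mode not in RATIO_MODES:
        raise ValueError(f"mode must be one of {RATIO_MODES}")
    ids = tuple(members) if members is not None else g.member_ids
    missing = [i for i in ids if i not in m.isoform_ids]
    if missing:
        raise KeyError(f"group members missing from matrix: {missing}")
    X = condition_slice(m, c).loc[list(ids)].to_numpy(dtype=float)
    ratios, defined = _ratio_vector(X, mode)
    return IsoformRatioTable(
        group=g,
        condition=c,
        member_ids=ids,
        ratios=tuple(float(r) for r in ratios) if defined else tuple(np.nan for _ in ids),
        defined=defined,
    )


def _ratio_vector(X: np.ndarray, mode: str) -> tuple[np.ndarray, bool]:
    """Ratio vector for a k x n_reps block; (nan vector, False) if undefined."""
    if mode == "condition-mean":
        means = X.mean(axis=1)
        tot = means.sum()
        if tot <= 0:
            return np.full(X.shape[0], np.nan), False
        return means / tot, True
    # per-replicate-mean
    colsum = X.sum(axis=0)
    ok = colsum > 0
    if not ok.any():
        return np.full(X.shape[0], np.nan), False
    R = X[:, ok] / colsum[ok]
    return R.mean(axis=1), True


def filter_low_ratio(
    flight: IsoformRatioTable,
    ground: IsoformRatioTable,
    epsilon: float = DEFAULT_EPSILON,
) -> list[str]:
    """Members surviving the low-ratio filter.

    A member is removed iff its ratio is strictly below epsilon in BOTH
    conditions (boundary ratio == epsilon is retained).  Both tables must
    describe the same group and member order.
    """
    if flight.group.key != ground.group.key or flight.member_ids != ground.member_ids:
        raise ValueError("ratio tables describe different groups/members")
    if not (flight.defined and ground.defined):
        raise ValueError("low-ratio filter requires defined ratio vectors")
    out = []
    for mid, rf, rg in zip(flight.member_ids, flight.ratios, ground.ratios):
        if rf < epsilon and rg < epsilon:
            continue
        out.append(mid)
    return out


# --------------------------------------------------------------------------
# permutation null
# --------------------------------------------------------------------------

def _exhaustive_masks(n_flight: int, n_total: int) -> np.ndarray:
    masks = np.zeros((comb(n_total, n_flight), n_total), dtype=bool)
    for i, idx in enumerate(combinations(range(n_total), n_flight)):
        masks[i, list(idx)] = True
    return masks


def _perm_statistics(X: np.ndarray, masks: np.ndarray, mode: str) -> np.ndarray:
    """sqrt-JSD of pseudo-flight vs pseudo-ground ratio vectors per mask.

    X is the k x n_total replicate FPKM block (flight columns first);
    masks is P x n_total boolean, True marking pseudo-flight columns.
    Assignments for which either pseudo-condition has zero group total
    yield NaN.
    """
    masks = masks.astype(float)
    nf = masks.sum(axis=1)
    ng = masks.shape[1] - nf
    if mode == "condition-mean":
        F = (X @ masks.T) / nf          # k x P mean per pseudo-flight
        G = (X @ (1.0 - masks).T) / ng
        Ft, Gt = F.sum(axis=0), G.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Pm = np.where(Ft > 0, F / Ft, np.nan)
            Qm = np.where(Gt > 0, G / Gt, np.nan)
    else:  # per-replicate-mean
        colsum = X.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(colsum > 0, X / colsum, np.nan)  # k x n
        okmask = (colsum > 0).astype(float)
        nf_ok = okmask @ masks.T
        ng_ok = okmask @ (1.0 - masks).T
        R0 = np.nan_to_num(R)
        with np.errstate(divide="ignore", invalid="ignore"):
            Pm = np.where(nf_ok > 0, (R0 @ masks.T) / nf_ok, np.nan)
            Qm = np.where(ng_ok > 0, (R0 @ (1.0 - masks).T) / ng_ok, np.nan)
    return _jsd_sqrt_columns(Pm, Qm)


def permutation_test(
    m: ExpressionMatrix,
    g: TssGroup,
    pair: tuple[Condition, Condition],
    *,
    members: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
    mode: str = "condition-mean",
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> PermutationResult:
    """Replicate-label permutation test of the sqrt-JSD splicing statistic.

    Labels (which replicate columns belong to flight) are permuted within
    the comparison pair; ratio vectors and the statistic are recomputed for
    each assignment.  When the number of distinct label assignments
    C(n_f + n_g, n_f) is at most ``exhaustive_limit`` every assignment is
    enumerated and p = #(assignment statistic >= observed) / #assignments —
    the enumeration includes the true labelling, so p is never 0.
    Otherwise ``n_perm`` random assignments are drawn and the +1-corrected
    estimate p = (1 + #(>= observed)) / (1 + n_perm) is returned.
    Deterministic given ``seed``.  Assignments whose statistic is undefined
    (a pseudo-condition with zero total) count against the observed
    statistic, which is conservative.
    """
    flight_c, ground_c = pair
    f_cols = m.samples_of(flight_c)
    g_cols = m.samples_of(ground_c)
    if len(f_cols) < 2 or len(g_cols) < 2:
        raise ValueError(
            f"permutation test requires >= 2 replicates per condition "
            f"(got {len(f_cols)} flight, {len(g_cols)} ground)"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = list(members) if members is not None else list(g.member_ids)
    if len(ids) < 2:
        raise ValueError("permutation test requires >= 2 group members")
    X = m.values.loc[ids, f_cols + g_cols].to_numpy(dtype=float)
    n_f, n_tot = len(f_cols), len(f_cols) + len(g_cols)

    observed_mask = np.zeros((1, n_tot), dtype=bool)
    observed_mask[0, :n_f] = True
    observed = float(_perm_statistics(X, observed_mask, mode)[0])
    if np.isnan(observed):
        raise ValueError(
            f"group {g.key}: statistic undefined (zero total expression in "
            "one condition); exclude via presence filtering first"
        )

    n_assign = comb(n_tot, n_f)
    if n_assign <= exhaustive_limit:
        masks = _exhaustive_masks(n_f, n_tot)
        stats = _perm_statistics(X, masks, mode)
        exceed = np.isnan(stats) | (stats >= observed - 1e-12)
        p = float(exceed.sum()) / n_assign
        return PermutationResult(observed, p, n_assign, True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masks = np.zeros((n_perm, n_tot), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n_tot, size=n_f, replace=False)] = True
    stats = _perm_statistics(X, masks, mode)
    exceed = np.isnan(stats) | (stats >= observed - 1e-12)
    p = (1.0 + float(exceed.sum())) / (1.0 + n_perm)
    return PermutationResult(observed, p, n_perm, False)


# --------------------------------------------------------------------------
# dAS calling
# --------------------------------------------------------------------------

def score_tss_group(
    m: ExpressionMatrix,
    g: TssGroup,
    pair: tuple[Condition, Condition],
    *,
    members: Sequence[str],
    ratio_members: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
    mode: str = "condition-mean",
) -> DasResult:
    """Run the sqrt-JSD permutation test for one TSS group.

    ``members`` are the group members surviving all upstream filters
    (presence and low-ratio); ``ratio_members`` is the universe the
    reported ratios are shares of (the presence-surviving working group;
    defaults to the full group).  Reported ratio vectors are NOT
    renormalised after the low-ratio removal, while the statistic uses the
    renormalised distributions over ``members`` only.
    """
    flight_c, ground_c = pair
    base = tuple(ratio_members) if ratio_members is not None else g.member_ids
    rf = isoform_ratios(m, g, flight_c, members=base, mode=mode)
    rg = isoform_ratios(m, g, ground_c, members=base, mode=mode)
    if not (rf.defined and rg.defined):
        raise ValueError(
            f"group {g.key}: ratios undefined in one condition (zero total); "
            "a presence-level difference is a PAV phenomenon, not testable here"
        )
    sel = [base.index(i) for i in members]
    rf_rep = tuple(rf.ratios[i] for i in sel)
    rg_rep = tuple(rg.ratios[i] for i in sel)
    perm = permutation_test(
        m, g, pair, members=members, n_perm=n_perm, seed=seed, mode=mode
    )
    switch = int(np.argmax(rf_rep)) != int(np.argmax(rg_rep))
    return DasResult(
        gene_id=g.gene_id,
        tss_key=g.key,
        member_ids=tuple(members),
        ratios_flight=rf_rep,
        ratios_ground=rg_rep,
        jsd_sqrt=perm.statistic,
        p_value=perm.p_value,
        n_assignments=perm.n_assignments,
        exhaustive=perm.exhaustive,
        switch=switch,
    )


def call_das(
    results: Iterable[DasResult], alpha: float = DEFAULT_ALPHA
) -> tuple[list[DasResult], set[str]]:
    """Benjamini–Hochberg adjust p-values and call dAS genes.

    FDR correction runs across all tested TSS groups of one comparison
    pair.  A gene is dAS when any of its groups has q <= alpha.  Returns
    the results (q_value / is_significant filled in) and the dAS gene set.
    """
    results = list(results)
    if not results:
        return [], set()
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pvals = np.array([r.p_value for r in results])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    das_genes: set[str] = set()
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        r.is_significant = bool(q <= alpha)
        if r.is_significant:
            das_genes.add(r.gene_id)
    return results, das_genes


def ecotype_overlap(
    das_by_background: Mapping[str, Iterable[str]],
) -> dict[str, object]:
    """Overlap bookkeeping for dAS gene sets pooled per genetic background.

    Input maps background (e.g. ecotype) -> pooled dAS gene set (union over
    ages).  Returns the pooled sets plus, for every background pair, the
    intersection and exclusive counts.
    """
    pools = {b: frozenset(gs) for b, gs in das_by_background.items()}
    if len(pools) < 2:
        raise ValueError("ecotype overlap requires >= 2 backgrounds")
    pairs = {}
    for a, b in combinations(sorted(pools), 2):
        inter = pools[a] & pools[b]
        pairs[(a, b)] = {
            "common": inter,
            f"{a}_only": pools[a] - pools[b],
            f"{b}_only": pools[b] - pools[a],
        }
    return {"pools": pools, "pairs": pairs}
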