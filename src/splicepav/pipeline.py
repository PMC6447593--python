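"""End-to-end orchestration of the PAV and dAS analyses.

The filter cascade is fixed: AS-gene filter -> per-condition presence
filter -> (for dAS) TSS grouping -> low-ratio filter -> permutation test.
Every stage's record count is logged and returned so the cascade is
auditable (counts are non-increasing through the filters), and every run
writes a machine-readable parameter echo next to its result files.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import (
    DEFAULT_ALPHA,
    DEFAULT_EPSILON,
    DasResult,
    call_das,
    ecotype_overlap,
    filter_low_ratio,
    isoform_ratios,
    score_tss_group,
)
from .pav import (
    ABSENCE_CAVEAT,
    DEFAULT_TAU,
    PavComparison,
    call_presence,
    compare_pav,
    multiway_overlap,
    restrict_to_as_isoforms,
)
from .quantification import Condition, ExpressionMatrix, load_matrix
from .transcriptome import (
    TssGroup,
    build_tss_groups,
    gene_of_map,
    identify_as_genes,
    parse_gtf,
)

logger = logging.getLogger("splicepav")


@dataclass
class RunConfig:
    """Thresholds, paths and modes of one analysis run.

    Defaults are the analysis' shipped operating point: presence threshold
    tau = 10 FPKM (inclusive, every replicate), low-ratio cutoff
    epsilon = 0.01 (strictly below, in both conditions), FDR level
    alpha = 0.05.
    """

    annotation: str = ""
    matrix: str = ""
    metadata: str = ""
    outdir: str = "results"
    tau: float = DEFAULT_TAU
    epsilon: float = DEFAULT_EPSILON
    alpha: float = DEFAULT_ALPHA
    n_perm: int = 1000
    seed: int = 0
    ratio_mode: str = "condition-mean"
    tss_window: int = 0

    def validate(self) -> None:
        if self.tau <= 0 or self.epsilon <= 0:
            raise ValueError("tau and epsilon must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def echo(self, path: Path) -> None:
        d = asdict(self)
        d["version"] = __version__
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def _header(rc: RunConfig) -> str:
    return (
        f"# splicepav {__version__} | tau={rc.tau} epsilon={rc.epsilon} "
        f"alpha={rc.alpha} n_perm={rc.n_perm} seed={rc.seed} "
        f"ratio_mode={rc.ratio_mode}\n"
    )


def _pair_tag(flight: Condition) -> str:
    return f"{flight.ecotype}_{flight.age_days}d"


@dataclass
class PavRunResult:
    comparisons: dict[tuple[str, int], PavComparison]
    cascade: dict[str, int]
    per_condition_present: dict[str, int]


@dataclass
class DasRunResult:
    results_by_pair: dict[tuple[str, int], list[DasResult]]
    das_genes_by_pair: dict[tuple[str, int], set[str]]
    cascade_by_pair: dict[tuple[str, int], dict[str, int]]
    pooled_by_ecotype: dict[str, frozenset[str]]


def _load_inputs(rc: RunConfig) -> tuple[ExpressionMatrix, set[str], dict[str, str], list[TssGroup]]:
    transcripts = parse_gtf(rc.annotation)
    matrix = load_matrix(rc.matrix, rc.metadata)
    as_genes = identify_as_genes(transcripts)
    gene_of = gene_of_map(transcripts)
    groups = build_tss_groups(transcripts, tss_window=rc.tss_window)
    return matrix, as_genes, gene_of, groups


def run_pav(rc: RunConfig, write: bool = True) -> PavRunResult:
    """Presence/absence-variation analysis over every flight/ground pair.

    Writes, per pair, present/absent/exclusive/common isoform lists, plus a
    multiway Venn-region count table across pairs (both for exclusive and
    for all-present sets, labelled accordingly).
    """
    rc.validate()
    outdir = Path(rc.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        rc.echo(outdir / "pav_params.yaml")
    matrix, as_genes, gene_of, _ = _load_inputs(rc)
    n_input = len(matrix.isoform_ids)
    as_matrix = restrict_to_as_isoforms(matrix, as_genes, gene_of)
    n_as = len(as_matrix.isoform_ids)
    logger.info("PAV cascade: %d input isoforms -> %d from AS parent genes", n_input, n_as)

    comparisons: dict[tuple[str, int], PavComparison] = {}
    per_condition_present: dict[str, int] = {}
    flight_only_sets: dict[str, frozenset[str]] = {}
    flight_present_sets: dict[str, frozenset[str]] = {}
    rows = []
    for flight_c, ground_c in as_matrix.condition_pairs():
        fl = call_presence(as_matrix, flight_c, rc.tau)
        gr = call_presence(as_matrix, ground_c, rc.tau)
        cmp_ = compare_pav(fl, gr)
        key = (flight_c.ecotype, flight_c.age_days)
        comparisons[key] = cmp_
        per_condition_present[flight_c.label] = len(fl.present_ids)
        per_condition_present[ground_c.label] = len(gr.present_ids)
        tag = _pair_tag(flight_c)
        flight_only_sets[tag] = cmp_.flight_only
        flight_present_sets[tag] = cmp_.flight_present
        logger.info(
            "pair %s: flight present %d, ground present %d, "
            "flight-only %d, ground-only %d, common %d",
            tag, len(fl.present_ids), len(gr.present_ids),
            len(cmp_.flight_only), len(cmp_.ground_only), len(cmp_.common),
        )
        for label, ids in (
            ("flight_present", fl.present_ids),
            ("ground_present", gr.present_ids),
            ("flight_only", cmp_.flight_only),
            ("ground_only", cmp_.ground_only),
            ("common", cmp_.common),
        ):
            for t in sorted(ids):
                rows.append((tag, label, t))

    if write:
        with open(outdir / "pav_lists.tsv", "w") as fh:
            fh.write(_header(rc))
            fh.write(f"# {ABSENCE_CAVEAT}\n")
            pd.DataFrame(rows, columns=["pair", "set", "isoform_id"]).to_csv(
                fh, sep="\t", index=False
            )
        overlap_rows = []
        if len(flight_only_sets) >= 2:
            for kind, sets in (
                ("flight_exclusive", flight_only_sets),
                ("flight_present", flight_present_sets),
            ):
                for region, n in multiway_overlap(sets).items():
                    overlap_rows.append((kind, "&".join(region), n))
        pd.DataFrame(overlap_rows, columns=["set_kind", "region", "count"]).to_csv(
            outdir / "pav_overlap.tsv", sep="\t", index=False
        )

    cascade = {"input_isoforms": n_input, "as_gene_isoforms": n_as}
    return PavRunResult(comparisons, cascade, per_condition_present)


def das_for_pair(
    matrix: ExpressionMatrix,
    groups: Sequence[TssGroup],
    pair: tuple[Condition, Condition],
    rc: RunConfig,
) -> tuple[list[DasResult], set[str], dict[str, int]]:
    """Filter cascade and permutation tests for one flight/ground pair.

    The working universe for each TSS group is its members present (min
    FPKM >= tau over replicates) in at least one condition of the pair;
    low-ratio members (< epsilon in both conditions) are then removed, and
    groups keeping >= 2 members are tested.  Groups whose total expression
    is zero in exactly one condition are excluded (counted as
    ``pav_like_groups``): their difference is an expression presence
    phenomenon, not a ratio change.
    """
    flight_c, ground_c = pair
    fl = call_presence(matrix, flight_c, rc.tau)
    gr = call_presence(matrix, ground_c, rc.tau)
    present_union = fl.present_ids | gr.present_ids
    rng = np.random.default_rng(np.random.SeedSequence([int(rc.seed), 0xD]))

    counts = {
        "groups_total": len(groups),
        "groups_multi_member": 0,
        "groups_after_presence": 0,
        "groups_after_ratio_filter": 0,
        "groups_tested": 0,
        "pav_like_groups": 0,
    }
    results: list[DasResult] = []
    for g in groups:
        if len(g.member_ids) < 2:
            continue
        counts["groups_multi_member"] += 1
        working = [i for i in g.member_ids if i in present_union]
        if len(working) < 2:
            continue
        counts["groups_after_presence"] += 1
        rf = isoform_ratios(matrix, g, flight_c, members=working, mode=rc.ratio_mode)
        rg = isoform_ratios(matrix, g, ground_c, members=working, mode=rc.ratio_mode)
        if not (rf.defined and rg.defined):
            counts["pav_like_groups"] += 1
            continue
        survivors = filter_low_ratio(rf, rg, rc.epsilon)
        if len(survivors) < 2:
            continue
        counts["groups_after_ratio_filter"] += 1
        res = score_tss_group(
            matrix, g, pair,
            members=survivors, ratio_members=working,
            n_perm=rc.n_perm, seed=rng, mode=rc.ratio_mode,
        )
        counts["groups_tested"] += 1
        results.append(res)
    results, das_genes = call_das(results, rc.alpha)
    return results, das_genes, counts


def run_das(rc: RunConfig, write: bool = True) -> DasRunResult:
    """Differential-alternative-splicing analysis over every condition pair.

    Writes per-pair result tables (gene, TSS group, members, per-condition
    ratios, sqrt-JSD, p, q, switch flag), per-pair summary counts of dAS
    genes and associated isoforms, and the per-ecotype pooled gene-set
    overlap table.
    """
    rc.validate()
    outdir = Path(rc.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        rc.echo(outdir / "das_params.yaml")
    matrix, as_genes, gene_of, groups = _load_inputs(rc)
    n_input = len(matrix.isoform_ids)
    as_matrix = restrict_to_as_isoforms(matrix, as_genes, gene_of)
    groups = [g for g in groups if all(i in as_matrix.isoform_ids for i in g.member_ids)]

    results_by_pair: dict[tuple[str, int], list[DasResult]] = {}
    das_by_pair: dict[tuple[str, int], set[str]] = {}
    cascade_by_pair: dict[tuple[str, int], dict[str, int]] = {}
    for pair in as_matrix.condition_pairs():
        key = (pair[0].ecotype, pair[0].age_days)
        results, das_genes, counts = das_for_pair(as_matrix, groups, pair, rc)
        counts = {"input_isoforms": n_input,
                  "as_gene_isoforms": len(as_matrix.isoform_ids), **counts}
        results_by_pair[key] = results
        das_by_pair[key] = das_genes
        cascade_by_pair[key] = counts
        logger.info(
            "pair %s_%dd: tested %d TSS groups, %d dAS genes (alpha=%.3g)",
            key[0], key[1], counts["groups_tested"], len(das_genes), rc.alpha,
        )

    pooled: dict[str, frozenset[str]] = {}
    for (eco, _age), genes in das_by_pair.items():
        pooled[eco] = pooled.get(eco, frozenset()) | frozenset(genes)

    if write:
        rows = []
        for (eco, age), results in sorted(results_by_pair.items()):
            for r in results:
                rows.append((
                    f"{eco}_{age}d", r.gene_id, r.tss_key,
                    ",".join(r.member_ids),
                    ",".join(f"{x:.6g}" for x in r.ratios_flight),
                    ",".join(f"{x:.6g}" for x in r.ratios_ground),
                    f"{r.jsd_sqrt:.6g}", f"{r.p_value:.6g}", f"{r.q_value:.6g}",
                    int(r.is_significant), int(r.switch),
                    r.n_assignments, int(r.exhaustive),
                ))
        with open(outdir / "das_results.tsv", "w") as fh:
            fh.write(_header(rc))
            pd.DataFrame(rows, columns=[
                "pair", "gene_id", "tss_key", "member_ids",
                "ratios_flight", "ratios_ground", "jsd_sqrt",
                "p_value", "q_value", "significant", "switch",
                "n_assignments", "exhaustive",
            ]).to_csv(fh, sep="\t", index=False)

        summary_rows = []
        for (eco, age), genes in sorted(das_by_pair.items()):
            iso = {
                i for r in results_by_pair[(eco, age)] if r.is_significant
                for i in r.member_ids
            }
            summary_rows.append((f"{eco}_{age}d", len(genes), len(iso)))
        pd.DataFrame(summary_rows, columns=["pair", "das_genes", "das_isoforms"]).to_csv(
            outdir / "das_summary.tsv", sep="\t", index=False
        )

        if len(pooled) >= 2:
            ov = ecotype_overlap(pooled)
            ov_rows = []
            for b, genes in sorted(ov["pools"].items()):
                ov_rows.append((f"{b}_pooled", len(genes), ";".join(sorted(genes))))
            for (a, b), d in sorted(ov["pairs"].items()):
                for label, genes in d.items():
                    ov_rows.append((f"{a}|{b}:{label}", len(genes), ";".join(sorted(genes))))
            pd.DataFrame(ov_rows, columns=["set", "count", "genes"]).to_csv(
                outdir / "das_ecotype_overlap.tsv", sep="\t", index=False
            )
        (outdir / "das_cascade.json").write_text(
            json.dumps({f"{k[0]}_{k[1]}d": v for k, v in cascade_by_pair.items()},
                       indent=2, sort_keys=True)
        )

    return DasRunResult(results_by_pair, das_by_pair, cascade_by_pair, pooled)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
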