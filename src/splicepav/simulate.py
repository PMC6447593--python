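"""Synthetic dataset generator emulating the spaceflight splicing design.

The generator produces a transcript annotation (GTF), an isoform x sample
FPKM matrix, sample metadata and ground-truth tables with the statistical
structure the downstream analysis assumes: 2 ecotypes x 2 ages x
{flight, ground} x 4 biological replicates by default, genes carrying 1-4
transcript isoforms distinguished by intron chain, a configurable fraction
of isoforms sharing their gene's transcription start site, planted
presence/absence (PAV) events and planted dominant-isoform ratio switches.

Noise model: multiplicative log-normal on FPKM (replicate value = condition
mean x exp(N(0, noise_log_sd))) — the simplest model producing
non-negative, right-skewed expression with replicate-level dispersion.
Library-size effects, gene-length bias and count-level sampling are not
simulated: the analysis consumes FPKM, so simulation happens directly at
FPKM level.

Planted truth is recoverable by construction: baseline expression values
falling inside a guard band around the presence threshold tau
(tau / e^(5*noise_log_sd) .. tau * e^(5*noise_log_sd)) are pushed to the
nearest band edge, so replicate noise essentially never flips a presence
call, and planted PAV levels (pav_high / pav_low) are required to clear
the band.  Real data have no such guard band; see the methods note for
what this does and does not let the tests demonstrate.

Planted dAS gene sets are drawn independently per ecotype with a small
forced overlap, so the demo dataset qualitatively reproduces
ecotype-specific splicing responses with little shared gene identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import exp, log
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .quantification import ExpressionMatrix, write_matrix
from .transcriptome import (
    ExonInterval,
    TranscriptModel,
    TssGroup,
    build_tss_groups,
    identify_as_genes,
    write_gtf,
)

GUARD_SIGMAS = 5.0  # half-width of the presence guard band, in noise SDs


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the synthetic design.

    Defaults emulate the spaceflight experiment's layout (2 ecotypes x
    2 ages x flight/ground x 4 replicates) with expression levels a
    practitioner would call realistic for plant RNA-seq: log-normal FPKM
    with median ~3 and a wide spread, ~20% replicate-level coefficient of
    variation, and planted effects whose margins clear the presence
    threshold by construction.
    """

    seed: int = 0
    n_genes: int = 500
    # most plant genes yield one or two assembled isoforms
    isoform_count_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.08}
    )
    shared_tss_prob: float = 0.6
    ecotypes: tuple[str, ...] = ("Col-0", "WS")
    ages_days: tuple[int, ...] = (4, 8)
    n_replicates: int = 4
    # log-normal baseline FPKM: median exp(1.1) ~ 3, sd 1.5 on the log scale
    baseline_log_mean: float = 1.1
    baseline_log_sd: float = 1.5
    noise_log_sd: float = 0.2
    # planted PAV events
    pav_fraction: float = 0.05
    pav_high: float = 50.0
    pav_low: float = 1.0
    # planted dominant-isoform switches
    switch_fraction: float = 0.08
    switch_displacement: float = 0.5
    n_switches: int | None = None  # exact per-ecotype count; overrides fraction
    switch_ecotype_overlap: float = 0.1
    # presence threshold the guard band is built around
    tau: float = 10.0
    chrom: str = "chrS"
    chrom_length: int = 500_000_000

    @property
    def guard_factor(self) -> float:
        return exp(GUARD_SIGMAS * self.noise_log_sd)

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise SimConfigError(f"seed must be an integer, got {type(self.seed).__name__}")
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise SimConfigError("n_replicates must be >= 2")
        w = self.isoform_count_weights
        if not w or any(k not in (1, 2, 3, 4) for k in w) or any(v < 0 for v in w.values()):
            raise SimConfigError("isoform_count_weights must weight counts in {1,2,3,4}")
        if sum(w.values()) <= 0:
            raise SimConfigError("isoform_count_weights must have positive mass")
        for name in ("shared_tss_prob", "pav_fraction", "switch_fraction",
                     "switch_ecotype_overlap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.switch_displacement <= 0.6:
            raise SimConfigError(
                "switch_displacement must be in (0, 0.6] so that every planted "
                "group member keeps a presence-safe share"
            )
        mg = self.guard_factor
        if self.pav_high < self.tau * mg:
            raise SimConfigError(
                f"pav_high={self.pav_high} must clear the presence guard band "
                f"(>= tau*{mg:.3g} = {self.tau * mg:.3g}) so planted presence is "
                "recoverable at the configured noise"
            )
        if self.pav_low > self.tau / mg:
            raise SimConfigError(
                f"pav_low={self.pav_low} must sit below the guard band "
                f"(<= tau/{mg:.3g} = {self.tau / mg:.3g})"
            )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["isoform_count_weights"] = {int(k): float(v) for k, v in d["isoform_count_weights"].items()}
        d["ecotypes"] = list(self.ecotypes)
        d["ages_days"] = [int(a) for a in self.ages_days]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
        if "ecotypes" in d:
            d["ecotypes"] = tuple(d["ecotypes"])
        if "ages_days" in d:
            d["ages_days"] = tuple(int(a) for a in d["ages_days"])
        if "isoform_count_weights" in d:
            d["isoform_count_weights"] = {int(k): float(v) for k, v in d["isoform_count_weights"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class PlantedSwitch:
    """Ground truth for one planted dominant-isoform ratio switch."""

    gene_id: str
    tss_key: str
    member_ids: tuple[str, ...]
    ratios_flight: tuple[float, ...]
    ratios_ground: tuple[float, ...]
    dominant_flight: str
    dominant_ground: str


@dataclass
class TruthTable:
    """Planted effects, keyed so recovery can be scored exactly."""

    # (ecotype, age) -> sets of condition-exclusive isoform ids
    pav_flight_exclusive: dict[tuple[str, int], frozenset[str]]
    pav_ground_exclusive: dict[tuple[str, int], frozenset[str]]
    # ecotype -> planted switches (applied at every age of that ecotype)
    switches_by_ecotype: dict[str, tuple[PlantedSwitch, ...]]

    def switch_genes(self, ecotype: str) -> frozenset[str]:
        return frozenset(s.gene_id for s in self.switches_by_ecotype.get(ecotype, ()))

    def all_switch_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for sw in self.switches_by_ecotype.values():
            out.update(s.gene_id for s in sw)
        return frozenset(out)


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

_EXON_LEN = 150
_INTRON_LEN = 100
_GENE_GAP = 1000
_TSS_SHIFT = 37  # 5'-end offset between isoforms with distinct TSSs


def generate_annotation(cfg: SimConfig) -> list[TranscriptModel]:
    """Deterministically generate gene/isoform structures on one chromosome.

    Isoforms of a multi-isoform gene differ by skipping distinct internal
    exons, so their intron chains are pairwise distinct and the AS-gene
    detector finds exactly the multi-isoform genes.  With probability
    ``shared_tss_prob`` all isoforms of a gene share the strand-aware 5'
    coordinate; otherwise each isoform receives its own TSS.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xA]))
    counts = sorted(cfg.isoform_count_weights)
    weights = np.array([cfg.isoform_count_weights[c] for c in counts], dtype=float)
    weights /= weights.sum()

    transcripts: list[TranscriptModel] = []
    cursor = 1001
    for gi in range(cfg.n_genes):
        gid = f"GENE{gi + 1:05d}"
        k = int(rng.choice(counts, p=weights))
        strand = "+" if rng.random() < 0.5 else "-"
        shared = (k == 1) or (rng.random() < cfg.shared_tss_prob)
        mono = k == 1 and rng.random() < 0.3
        n_ex = 1 if mono else int(max(k + 2, 4))
        starts = [cursor + j * (_EXON_LEN + _INTRON_LEN) for j in range(n_ex)]
        exons_full = [
            ExonInterval(cfg.chrom, s, s + _EXON_LEN - 1) for s in starts
        ]
        span_end = exons_full[-1].end
        if span_end + _GENE_GAP > cfg.chrom_length:
            raise SimConfigError(
                f"gene layout exceeds chromosome length {cfg.chrom_length}; "
                "increase chrom_length (larger coordinate space) or reduce n_genes"
            )
        for j in range(k):
            exons = list(exons_full) if j == 0 else (
                exons_full[:j] + exons_full[j + 1:]  # skip internal exon j
            )
            if not shared and j > 0:
                off = j * _TSS_SHIFT
                if strand == "+":
                    e0 = exons[0]
                    exons[0] = ExonInterval(e0.chrom, e0.start + off, e0.end)
                else:
                    el = exons[-1]
                    exons[-1] = ExonInterval(el.chrom, el.start, el.end - off)
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gid}.i{j + 1}",
                    gene_id=gid,
                    chrom=cfg.chrom,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
        cursor = span_end + _GENE_GAP
    return transcripts


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def _guard_push(base: np.ndarray, tau: float, mg: float) -> np.ndarray:
    """Push baseline values out of the presence ambiguity band.

    Values in (tau/mg, tau*mg) are moved to the nearest band edge (values
    below tau down to tau/mg, values at or above tau up to tau*mg), so no
    null isoform straddles the presence threshold under replicate noise.
    """
    lo, hi = tau / mg, tau * mg
    out = base.copy()
    in_band = (out > lo) & (out < hi)
    out[in_band & (out < tau)] = lo
    out[in_band & (out >= tau)] = hi
    return out


def _switch_ratio_vectors(
    n_members: int, displacement: float
) -> tuple[np.ndarray, np.ndarray]:
    """True flight/ground ratio vectors for a planted switch group.

    The first two members form the switching pair; remaining members keep
    a fixed minor share (0.1 each).  The dominant member's ratio exceeds
    the runner-up's by ``displacement`` and the two swap between
    treatments, preserving the group total.
    """
    n_rest = n_members - 2
    share = 1.0 - 0.1 * n_rest
    hi = (share + displacement) / 2.0
    lo = (share - displacement) / 2.0
    flight = np.array([hi, lo] + [0.1] * n_rest)
    ground = np.array([lo, hi] + [0.1] * n_rest)
    return flight, ground


def generate_expression(
    cfg: SimConfig, transcripts: Sequence[TranscriptModel]
) -> tuple[ExpressionMatrix, TruthTable]:
    """Generate the FPKM matrix, metadata and truth for an annotation.

    Per ecotype x age the design holds one flight/ground pair with
    ``n_replicates`` samples each.  Null isoforms share one guard-banded
    baseline across all conditions; planted PAV isoforms sit at
    ``pav_high`` in every replicate of one treatment and ``pav_low`` in the
    other; planted switch groups carry swapped dominant/runner-up ratio
    vectors between treatments at a high, presence-safe group total.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xE]))
    iso_ids = [t.transcript_id for t in transcripts]
    iso_index = {t: i for i, t in enumerate(iso_ids)}
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    n_iso = len(iso_ids)
    mg = cfg.guard_factor

    # ---- sample layout ----
    meta_rows = []
    columns: list[str] = []
    for eco in cfg.ecotypes:
        for age in cfg.ages_days:
            for tr in ("flight", "ground"):
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{eco}_{age}d_{tr}_{rep}"
                    meta_rows.append((sid, eco, int(age), tr, rep))
                    columns.append(sid)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "ecotype", "age_days", "treatment", "replicate"]
    ).set_index("sample_id")

    # ---- baselines (global per isoform), guard-banded ----
    base = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_iso))
    base = _guard_push(base, cfg.tau, mg)
    means = np.tile(base[:, None], (1, len(columns)))
    col_of = {c: j for j, c in enumerate(columns)}

    def cols_of(eco: str, age: int, tr: str) -> list[int]:
        return [
            col_of[f"{eco}_{age}d_{tr}_{r}"] for r in range(1, cfg.n_replicates + 1)
        ]

    # ---- planted switches (per ecotype, both ages) ----
    groups = build_tss_groups(transcripts)
    eligible_groups = [g for g in groups if len(g.member_ids) >= 2]
    # one group per gene keeps gene-level truth unambiguous
    seen_genes: set[str] = set()
    uniq_groups = []
    for g in eligible_groups:
        if g.gene_id not in seen_genes:
            uniq_groups.append(g)
            seen_genes.add(g.gene_id)
    n_eligible = len(uniq_groups)
    n_sw = (
        int(cfg.n_switches)
        if cfg.n_switches is not None
        else int(round(cfg.switch_fraction * n_eligible))
    )
    if n_sw > 0 and cfg.switch_displacement > 0.8 - 0.2:  # defensive; validate() bounds it
        raise SimConfigError("switch_displacement too large for planted groups")
    switches_by_ecotype: dict[str, tuple[PlantedSwitch, ...]] = {}
    chosen_union: set[str] = set()
    if n_sw > 0:
        if n_sw > n_eligible:
            raise SimConfigError(
                f"cannot plant {n_sw} switches: only {n_eligible} eligible "
                "multi-member TSS groups (singleton groups cannot switch)"
            )
        order = list(rng.permutation(n_eligible))
        n_shared = 0
        if len(cfg.ecotypes) >= 2 and n_sw >= 1:
            n_shared = max(1, int(round(cfg.switch_ecotype_overlap * n_sw)))
            n_shared = min(n_shared, n_sw)
        shared_idx = order[:n_shared]
        pos = n_shared
        for eco in cfg.ecotypes:
            own = order[pos: pos + (n_sw - n_shared)]
            pos += n_sw - n_shared
            if len(own) < n_sw - n_shared:
                raise SimConfigError(
                    "not enough eligible TSS groups for per-ecotype switch sets; "
                    "reduce switch_fraction/n_switches or raise n_genes"
                )
            idxs = shared_idx + own
            planted = []
            for gi_idx in idxs:
                g = uniq_groups[gi_idx]
                rf, rgr = _switch_ratio_vectors(
                    len(g.member_ids), cfg.switch_displacement
                )
                planted.append(
                    PlantedSwitch(
                        gene_id=g.gene_id,
                        tss_key=g.key,
                        member_ids=g.member_ids,
                        ratios_flight=tuple(float(x) for x in rf),
                        ratios_ground=tuple(float(x) for x in rgr),
                        dominant_flight=g.member_ids[int(np.argmax(rf))],
                        dominant_ground=g.member_ids[int(np.argmax(rgr))],
                    )
                )
                chosen_union.add(g.gene_id)
            switches_by_ecotype[eco] = tuple(planted)

        # presence-safe group total: the smallest member share must clear
        # the guard band in every replicate
        min_share = min(0.1, (1.0 - 0.2 - cfg.switch_displacement) / 2.0)
        t_min = 1.2 * cfg.tau * mg / min_share
        for eco in cfg.ecotypes:
            for sw in switches_by_ecotype.get(eco, ()):
                for age in cfg.ages_days:
                    total = float(np.exp(rng.uniform(log(t_min), log(3 * t_min))))
                    for tr, ratios in (("flight", sw.ratios_flight),
                                       ("ground", sw.ratios_ground)):
                        cols = cols_of(eco, age, tr)
                        for mid, r in zip(sw.member_ids, ratios):
                            means[iso_index[mid], cols] = total * r

    # ---- planted PAV (per ecotype x age pair) ----
    as_genes = identify_as_genes(transcripts)
    pav_eligible = [
        t for t in iso_ids
        if gene_of[t] in as_genes and gene_of[t] not in chosen_union
    ]
    pav_fl: dict[tuple[str, int], frozenset[str]] = {}
    pav_gr: dict[tuple[str, int], frozenset[str]] = {}
    for eco in cfg.ecotypes:
        for age in cfg.ages_days:
            n_pav = int(round(cfg.pav_fraction * len(pav_eligible)))
            if n_pav == 0:
                pav_fl[(eco, int(age))] = frozenset()
                pav_gr[(eco, int(age))] = frozenset()
                continue
            picked = rng.choice(len(pav_eligible), size=n_pav, replace=False)
            picked_ids = [pav_eligible[i] for i in sorted(picked)]
            fl_ids = picked_ids[0::2]
            gr_ids = picked_ids[1::2]
            for ids, hi_tr, lo_tr in ((fl_ids, "flight", "ground"),
                                      (gr_ids, "ground", "flight")):
                hi_cols = cols_of(eco, age, hi_tr)
                lo_cols = cols_of(eco, age, lo_tr)
                for t in ids:
                    means[iso_index[t], hi_cols] = cfg.pav_high
                    means[iso_index[t], lo_cols] = cfg.pav_low
            pav_fl[(eco, int(age))] = frozenset(fl_ids)
            pav_gr[(eco, int(age))] = frozenset(gr_ids)

    # ---- replicate noise ----
    noise = (
        np.exp(rng.normal(0.0, cfg.noise_log_sd, means.shape))
        if cfg.noise_log_sd > 0
        else np.ones_like(means)
    )
    values = pd.DataFrame(means * noise, index=pd.Index(iso_ids, name="isoform_id"),
                          columns=columns)
    matrix = ExpressionMatrix(values, meta)
    truth = TruthTable(
        pav_flight_exclusive=pav_fl,
        pav_ground_exclusive=pav_gr,
        switches_by_ecotype=switches_by_ecotype,
    )
    return matrix, truth


# --------------------------------------------------------------------------
# dataset I/O
# --------------------------------------------------------------------------

def write_truth(truth: TruthTable, outdir: str | Path) -> None:
    outdir = Path(outdir)
    rows = []
    for (eco, age), ids in sorted(truth.pav_flight_exclusive.items()):
        for t in sorted(ids):
            rows.append((eco, age, "flight", t))
    for (eco, age), ids in sorted(truth.pav_ground_exclusive.items()):
        for t in sorted(ids):
            rows.append((eco, age, "ground", t))
    pd.DataFrame(rows, columns=["ecotype", "age_days", "exclusive_to", "isoform_id"]).to_csv(
        outdir / "truth_pav.tsv", sep="\t", index=False
    )
    rows = []
    for eco, sws in sorted(truth.switches_by_ecotype.items()):
        for sw in sws:
            rows.append(
                (
                    eco,
                    sw.gene_id,
                    sw.tss_key,
                    ",".join(sw.member_ids),
                    ",".join(f"{r:.6g}" for r in sw.ratios_flight),
                    ",".join(f"{r:.6g}" for r in sw.ratios_ground),
                    sw.dominant_flight,
                    sw.dominant_ground,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "ecotype", "gene_id", "tss_key", "member_ids",
            "ratios_flight", "ratios_ground", "dominant_flight", "dominant_ground",
        ],
    ).to_csv(outdir / "truth_switches.tsv", sep="\t", index=False)


def generate_dataset(cfg: SimConfig, outdir: str | Path) -> tuple[
    list[TranscriptModel], ExpressionMatrix, TruthTable
]:
    """Generate and write a complete synthetic dataset to ``outdir``.

    Emits annotation.gtf, matrix.tsv, samples.tsv, truth_pav.tsv,
    truth_switches.tsv and a config.yaml echo.  Byte-identical for
    identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = generate_annotation(cfg)
    matrix, truth = generate_expression(cfg, transcripts)
    write_gtf(transcripts, outdir / "annotation.gtf")
    write_matrix(matrix, outdir / "matrix.tsv", outdir / "samples.tsv")
    write_truth(truth, outdir)
    cfg.to_yaml(outdir / "config.yaml")
    return transcripts, matrix, truth


# --------------------------------------------------------------------------
# focused simulators for calibration studies
# --------------------------------------------------------------------------

def null_group_dataset(
    n_groups: int,
    *,
    seed: int = 0,
    n_replicates: int = 4,
    noise_log_sd: float = 0.2,
    member_counts: Sequence[int] = (2, 3),
    tau: float = 10.0,
) -> tuple[ExpressionMatrix, list[TssGroup]]:
    """Null TSS groups for permutation-test calibration.

    Every group has a shared true ratio vector between flight and ground
    (no planted switch); member mean FPKMs are drawn above the presence
    guard band so all groups are testable, and replicates add log-normal
    noise.  Returns a single-pair (one ecotype, one age) matrix plus the
    group list.  Groups are synthetic constructs, not tied to an
    annotation: each carries a nominal TSS.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x17]))
    mg = exp(GUARD_SIGMAS * noise_log_sd)
    floor = 1.5 * tau * mg
    cols = [f"sim_1d_{tr}_{r}" for tr in ("flight", "ground")
            for r in range(1, n_replicates + 1)]
    meta = pd.DataFrame(
        [(c, "sim", 1, c.split("_")[2], int(c.split("_")[3])) for c in cols],
        columns=["sample_id", "ecotype", "age_days", "treatment", "replicate"],
    ).set_index("sample_id")

    ids, rows, groups = [], [], []
    for gi in range(n_groups):
        k = int(rng.choice(list(member_counts)))
        gid = f"NULL{gi + 1:05d}"
        member_ids = tuple(f"{gid}.i{j + 1}" for j in range(k))
        member_means = np.exp(rng.uniform(log(floor), log(100 * tau), k))
        noise = np.exp(rng.normal(0.0, noise_log_sd, (k, len(cols))))
        block = member_means[:, None] * noise
        ids.extend(member_ids)
        rows.append(block)
        groups.append(TssGroup(gid, "chrS", "+", 1 + gi * 10, member_ids))
    values = pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="isoform_id"), columns=cols
    )
    return ExpressionMatrix(values, meta), groups
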