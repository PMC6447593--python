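"""Shared fixtures: tiny hand-built annotations and expression matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from splicepav import ExonInterval, TranscriptModel, ExpressionMatrix, Condition


def tx(tid: str, gid: str, exons, strand: str = "+", chrom: str = "chr1") -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        exons=tuple(ExonInterval(chrom, s, e) for s, e in exons),
    )


def one_pair_matrix(values: dict[str, list[float]], n_rep: int = 4,
                    ecotype: str = "Col-0", age: int = 4) -> ExpressionMatrix:
    """Matrix for a single flight/ground pair from per-isoform column lists.

    ``values[iso]`` holds n_rep flight values followed by n_rep ground values.
    """
    cols = [f"{ecotype}_{age}d_{tr}_{r}" for tr in ("flight", "ground")
            for r in range(1, n_rep + 1)]
    meta = pd.DataFrame(
        [(c, ecotype, age, c.rsplit("_", 2)[1], int(c.rsplit("_", 2)[2])) for c in cols],
        columns=["sample_id", "ecotype", "age_days", "treatment", "replicate"],
    ).set_index("sample_id")
    vals = pd.DataFrame(
        {c: [values[i][j] for i in values] for j, c in enumerate(cols)},
        index=pd.Index(list(values), name="isoform_id"),
    )
    return ExpressionMatrix(vals, meta)


@pytest.fixture
def pair() -> tuple[Condition, Condition]:
    return Condition("Col-0", 4, "flight"), Condition("Col-0", 4, "ground")


# ---------------------------------------------------------------------------
# hand-built 12-isoform toy exercising every filter of the cascade
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_dataset():
    """12 isoforms / 6 genes covering every filter branch.

    G1 three isoforms, shared TSS, distinct chains; t1c is present but holds
       < 1% of the group in both conditions (low-ratio removal).
    G2 two isoforms, shared TSS; t2b dips to 9.999 in one replicate of each
       condition (sub-threshold replicate -> absent everywhere).
    G3 single isoform (AS-gene filter removes it).
    G4 two isoforms with identical intron chains, different 3' ends (not
       structurally unique -> AS-gene filter removes both).
    G5 two structurally distinct isoforms with different TSSs (singleton
       TSS groups -> never ratio-tested).
    G6 two isoforms, shared TSS; t6a sits exactly at FPKM 10.0 in every
       flight replicate (inclusive presence boundary) and its flight ratio
       is exactly 0.01 (boundary retained by the strict < rule).
    """
    transcripts = [
        tx("t1a", "G1", [(100, 200), (300, 400), (500, 600), (700, 800)]),
        tx("t1b", "G1", [(100, 200), (500, 600), (700, 800)]),
        tx("t1c", "G1", [(100, 200), (300, 400), (700, 800)]),
        tx("t2a", "G2", [(1000, 1100), (1200, 1300)]),
        tx("t2b", "G2", [(1000, 1100), (1250, 1300)]),
        tx("t3", "G3", [(2000, 2100), (2200, 2300)]),
        tx("t4a", "G4", [(3000, 3100), (3200, 3300)]),
        tx("t4b", "G4", [(3000, 3100), (3200, 3350)]),
        tx("t5a", "G5", [(4000, 4100), (4200, 4300)]),
        tx("t5b", "G5", [(4050, 4100), (4210, 4300)]),
        tx("t6a", "G6", [(5000, 5100), (5200, 5300)]),
        tx("t6b", "G6", [(5000, 5100), (5250, 5300)]),
    ]
    flat = lambda f, g: [f] * 4 + [g] * 4  # noqa: E731
    values = {
        "t1a": flat(2000.0, 1000.0),
        "t1b": flat(3000.0, 4000.0),
        "t1c": flat(12.0, 11.0),     # present, but ratio 12/5012 and 11/5011
        "t2a": flat(50.0, 50.0),
        "t2b": [50.0, 50.0, 50.0, 9.999, 50.0, 50.0, 50.0, 9.999],
        "t3": flat(100.0, 100.0),
        "t4a": flat(100.0, 100.0),
        "t4b": flat(100.0, 100.0),
        "t5a": flat(20.0, 20.0),
        "t5b": flat(20.0, 20.0),
        "t6a": flat(10.0, 90.0),     # boundary presence; flight ratio 0.01
        "t6b": flat(990.0, 910.0),
    }
    matrix = one_pair_matrix(values)
    expected = {
        "input_isoforms": 12,
        "as_gene_isoforms": 9,          # G3 (1) and G4 (2) removed
        "as_genes": {"G1", "G2", "G5", "G6"},
        "flight_present": 8,            # all AS isoforms except t2b
        "ground_present": 8,
        "groups_total": 5,              # G1, G2, G6 + two G5 singletons
        "groups_multi_member": 3,       # G1, G2, G6
        "groups_after_presence": 2,     # G2 collapses to one member
        "groups_after_ratio_filter": 2,  # G1 drops t1c but keeps 2 members
        "groups_tested": 2,
        "tested_members": {"G1": ["t1a", "t1b"], "G6": ["t6a", "t6b"]},
    }
    return transcripts, matrix, expected


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
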