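"""Seedable generators for synthetic methylation cohorts and translocation junctions.

The generators emulate the data structures an EPIC-array study of
IGH::BCL3-translocated CLL works with, at desk scale:

* a beta-value matrix (CpGs x samples, values in [0,1]) for a case group and
  several control groups, with a planted set of differentially methylated
  CpGs (overwhelmingly hypomethylated, concentrated in heterochromatin-
  associated late-B-cell-differentiation modules),
* tumor purity mixing (observed beta = purity * tumor + (1-purity) * normal),
* follow-up sample pairs with elevated within-patient correlation,
* log2-ratio-like intensity tracks with planted copy-number segments,
* breakpoint-junction records produced by a class-switch-recombination-like
  or an aberrant-V(D)J-like mechanism, on a small synthetic two-chromosome
  reference with embedded recombination-signal-sequence motifs.

Everything is deterministic for a fixed seed; one master seed can be split
into per-component streams with :func:`child_seed`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_CASE = "BCL3"
CONTROL_GROUPS = ("CLL_U", "CLL_IGTRANS", "PC_LIKE")

CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23))

# Deterministic rule table mapping module membership to chromatin state.
# Modules 8, 9 and 13 mark heterochromatic demethylation during late B-cell
# differentiation; low-numbered modules mark active regions.
MODULE_STATE_RULES: dict[int, str] = {
    1: "active",
    2: "active",
    3: "active",
    4: "other",
    5: "other",
    6: "other",
    7: "other",
    8: "heterochromatin",
    9: "heterochromatin",
    10: "other",
    11: "other",
    12: "active",
    13: "heterochromatin",
}

HETEROCHROMATIN_MODULES = (8, 9, 13)

RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAACC"


def child_seed(master: int, offset: int) -> int:
    """Derive a component seed from a master seed; stays below 2**31."""
    return int((int(master) * 1_000_003 + offset) % 2_147_483_647)


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Parameters of a synthetic methylation cohort.

    ``delta_beta`` is the planted beta-scale group difference at truth CpGs;
    ``precision`` is the concentration of the beta-distributed measurement
    noise (``inf`` disables noise); ``purity_range`` bounds the uniform
    tumor-cell fraction of case samples.
    """

    n_cases: int = 80
    n_controls: int = 32
    n_cpgs: int = 20000
    n_hypo: int = 1960
    n_hyper: int = 25
    delta_beta: float = 0.35
    precision: float = 50.0
    purity_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0
    control_groups: tuple[str, ...] = CONTROL_GROUPS

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_cpgs, self.n_hypo, self.n_hyper) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_hypo + self.n_hyper > self.n_cpgs:
            raise ValueError("planted DMC count exceeds n_cpgs")
        if not (0.0 < self.delta_beta < 1.0):
            raise ValueError("delta_beta must lie in (0, 1)")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("purity_range must be within [0, 1]")
        unknown = set(self.control_groups) - set(CONTROL_GROUPS)
        if unknown:
            raise ValueError(f"unknown control groups: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# CpG annotation
# ---------------------------------------------------------------------------


def generate_annotation(n_cpgs: int, seed: int) -> pd.DataFrame:
    """Annotate ``n_cpgs`` CpGs on a small synthetic genome.

    Returns a BED-like frame (chrom, start, end, cpg_id, module, state,
    gene) with 1-based inclusive coordinates, module membership in
    {1..13, 'none'} and chromatin state {heterochromatin, active, other}.
    States of module-assigned CpGs follow :data:`MODULE_STATE_RULES`.
    """
    if n_cpgs < 100:
        raise ValueError("n_cpgs must be at least 100")
    rng = np.random.default_rng(seed)

    chrom_of = np.sort(rng.integers(0, len(CHROMOSOMES), size=n_cpgs))
    starts = np.empty(n_cpgs, dtype=np.int64)
    for c in range(len(CHROMOSOMES)):
        mask = chrom_of == c
        k = int(mask.sum())
        # contiguous placement with jittered ~500 bp spacing
        gaps = rng.integers(200, 800, size=k)
        starts[mask] = 1 + np.cumsum(gaps)

    module_pool = np.array([0] + list(range(1, 14)))
    # none, modules 1..7 at 0.02, module 8 -> 0.10, 9 -> 0.06, 10..12 -> 0.02, 13 -> 0.03
    weights = np.array([0.55, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.10, 0.06, 0.02, 0.02, 0.02, 0.03])
    weights = weights / weights.sum()
    modules = rng.choice(module_pool, size=n_cpgs, p=weights)

    states = np.empty(n_cpgs, dtype=object)
    none_mask = modules == 0
    for m, s in MODULE_STATE_RULES.items():
        states[modules == m] = s
    states[none_mask] = rng.choice(
        ["heterochromatin", "active", "other"], size=int(none_mask.sum()), p=[0.3, 0.3, 0.4]
    )

    genes = np.array([f"GENE{1 + i // 20:05d}" for i in range(n_cpgs)], dtype=object)

    ann = pd.DataFrame(
        {
            "chrom": [CHROMOSOMES[c] for c in chrom_of],
            "start": starts,
            "end": starts + 1,
            "cpg_id": [f"cg{i:08d}" for i in range(1, n_cpgs + 1)],
            "module": np.where(none_mask, "none", modules.astype(str)),
            "state": states,
            "gene": genes,
        }
    )
    return ann.set_index("cpg_id", drop=False)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _beta_noise(rng: np.random.Generator, means: np.ndarray, precision: float) -> np.ndarray:
    if not np.isfinite(precision):
        return means.copy()
    m = np.clip(means, 1e-6, 1.0 - 1e-6)
    return rng.beta(m * precision, (1.0 - m) * precision)


def generate_cohort(
    config: CohortConfig, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (beta matrix, sample sheet, DMC truth table).

    Hypomethylated truth CpGs are drawn 90% from heterochromatin-state CpGs
    in modules 8/9/13 and 10% elsewhere, emulating the concentration of the
    translocation-associated methylation loss in late-differentiation
    heterochromatic modules.  The plasma-cell-like control group shares a
    partial (80%) version of the hypomethylation.  Observed values mix the
    tumor profile with a normal background at the sample's purity, then add
    beta-distributed noise at ``config.precision`` and clamp to [0, 1].
    """
    if len(annotation) < config.n_cpgs:
        raise ValueError("annotation has fewer CpGs than config.n_cpgs")
    ann = annotation.iloc[: config.n_cpgs]
    cpg_ids = ann["cpg_id"].to_numpy()
    rng = np.random.default_rng(config.seed)

    state = ann["state"].to_numpy()
    module = ann["module"].to_numpy()

    # baseline (normal background / other-CLL) means: heterochromatin high,
    # active low, other mixed — the usual bimodal methylome shape
    baseline = np.empty(config.n_cpgs)
    het = state == "heterochromatin"
    act = state == "active"
    oth = ~(het | act)
    baseline[het] = rng.uniform(0.60, 0.95, size=int(het.sum()))
    baseline[act] = rng.uniform(0.05, 0.30, size=int(act.sum()))
    baseline[oth] = rng.uniform(0.15, 0.85, size=int(oth.sum()))

    # --- choose truth CpGs -------------------------------------------------
    het_mod = het & np.isin(module, [str(m) for m in HETEROCHROMATIN_MODULES])
    idx_all = np.arange(config.n_cpgs)
    n_hypo_pref = int(round(0.9 * config.n_hypo))
    pref_pool = idx_all[het_mod]
    if len(pref_pool) < n_hypo_pref:
        n_hypo_pref = len(pref_pool)
    hypo_pref = rng.choice(pref_pool, size=n_hypo_pref, replace=False)
    rest_pool = np.setdiff1d(idx_all, hypo_pref)
    hypo_rest = rng.choice(rest_pool, size=config.n_hypo - n_hypo_pref, replace=False)
    hypo_idx = np.sort(np.concatenate([hypo_pref, hypo_rest]))
    hyper_pool = np.setdiff1d(idx_all, hypo_idx)
    # hypermethylated truth CpGs need headroom above the baseline
    low_first = hyper_pool[np.argsort(baseline[hyper_pool])]
    hyper_idx = np.sort(low_first[: config.n_hyper])

    delta = config.delta_beta
    # shift baselines that leave no room for the planted effect
    margin = 0.02
    bad_lo = hypo_idx[baseline[hypo_idx] < delta + margin]
    if len(bad_lo):
        warnings.warn(f"shifted {len(bad_lo)} baselines up to fit planted hypo effect")
        baseline[bad_lo] = delta + margin + rng.uniform(0, 0.05, size=len(bad_lo))
    bad_hi = hyper_idx[baseline[hyper_idx] > 1.0 - delta - margin]
    if len(bad_hi):
        warnings.warn(f"shifted {len(bad_hi)} baselines down to fit planted hyper effect")
        baseline[bad_hi] = 1.0 - delta - margin - rng.uniform(0, 0.05, size=len(bad_hi))

    case_mean = baseline.copy()
    case_mean[hypo_idx] -= delta
    case_mean[hyper_idx] += delta

    pc_mean = baseline.copy()
    pc_mean[hypo_idx] -= 0.8 * delta  # plasma-cell-like partial hypomethylation

    group_means = {
        GROUP_CASE: case_mean,
        "CLL_U": baseline,
        "CLL_IGTRANS": baseline,
        "PC_LIKE": pc_mean,
    }

    # --- samples -----------------------------------------------------------
    sample_ids: list[str] = []
    groups: list[str] = []
    prefixes = {GROUP_CASE: "BCL3", "CLL_U": "CLLU", "CLL_IGTRANS": "IGT", "PC_LIKE": "PC"}
    for i in range(config.n_cases):
        sample_ids.append(f"BCL3_{i + 1:03d}")
        groups.append(GROUP_CASE)
    for g in config.control_groups:
        for i in range(config.n_controls):
            sample_ids.append(f"{prefixes[g]}_{i + 1:03d}")
            groups.append(g)

    n_samples = len(sample_ids)
    lo, hi = config.purity_range
    purity = rng.uniform(lo, hi, size=n_samples)

    values = np.empty((config.n_cpgs, n_samples))
    for j, (sid, g) in enumerate(zip(sample_ids, groups)):
        tumor = group_means[g]
        mean_j = purity[j] * tumor + (1.0 - purity[j]) * baseline
        values[:, j] = _beta_noise(rng, mean_j, config.precision)
    np.clip(values, 0.0, 1.0, out=values)

    beta = pd.DataFrame(values, index=cpg_ids, columns=sample_ids)
    beta.index.name = "cpg_id"

    ighv = ["unmutated" if g != "PC_LIKE" else "mutated" for g in groups]
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "ighv_status": ighv,
            "purity": purity,
            "followup_of": [""] * n_samples,
            "time_offset": [0.0] * n_samples,
        }
    ).set_index("sample_id", drop=False)

    truth = pd.DataFrame(
        {
            "cpg_id": np.concatenate([cpg_ids[hypo_idx], cpg_ids[hyper_idx]]),
            "direction": ["hypo"] * len(hypo_idx) + ["hyper"] * len(hyper_idx),
            "planted_delta": np.concatenate(
                [np.full(len(hypo_idx), -delta), np.full(len(hyper_idx), delta)]
            ),
        }
    ).set_index("cpg_id", drop=False)

    return beta, sheet, truth


def generate_followups(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    n_pairs: int,
    within_noise: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append follow-up samples: parent profile plus small independent noise.

    Follow-ups copy the first ``n_pairs`` case samples; within-patient
    correlation therefore exceeds between-patient correlation in
    expectation whenever ``within_noise`` is small relative to the
    biological spread.
    """
    cases = sheet.loc[sheet["group"] == GROUP_CASE, "sample_id"].tolist()
    if n_pairs > len(cases):
        raise ValueError("n_pairs exceeds number of case samples")
    rng = np.random.default_rng(seed)
    new_cols = {}
    rows = []
    for parent in cases[:n_pairs]:
        child = f"{parent}_F1"
        profile = beta[parent].to_numpy() + rng.normal(0.0, within_noise, size=len(beta))
        new_cols[child] = np.clip(profile, 0.0, 1.0)
        rows.append(
            {
                "sample_id": child,
                "group": GROUP_CASE,
                "ighv_status": sheet.loc[parent, "ighv_status"],
                "purity": float(sheet.loc[parent, "purity"]),
                "followup_of": parent,
                "time_offset": float(rng.uniform(1.0, 10.0)),
            }
        )
    beta2 = pd.concat([beta, pd.DataFrame(new_cols, index=beta.index)], axis=1)
    sheet2 = pd.concat([sheet, pd.DataFrame(rows).set_index("sample_id", drop=False)])
    return beta2, sheet2


def generate_intensity(
    annotation: pd.DataFrame,
    sample_ids: Sequence[str],
    cnv_spec: Sequence[tuple[str, float]],
    noise_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Log2-ratio-like intensity matrix with planted per-chromosome shifts.

    Neutral probes center at 0; probes on a chromosome named in
    ``cnv_spec`` center at the given shift.  The same shifts apply to every
    listed sample (generate references with an empty spec).
    """
    chroms = set(annotation["chrom"])
    for chrom, _ in cnv_spec:
        if chrom not in chroms:
            raise ValueError(f"unknown chromosome in cnv_spec: {chrom}")
    rng = np.random.default_rng(seed)
    center = np.zeros(len(annotation))
    for chrom, shift in cnv_spec:
        center[(annotation["chrom"] == chrom).to_numpy()] += shift
    vals = center[:, None] + rng.normal(0.0, noise_sd, size=(len(annotation), len(sample_ids)))
    out = pd.DataFrame(vals, index=annotation["cpg_id"].to_numpy(), columns=list(sample_ids))
    out.index.name = "probe_id"
    return out


# ---------------------------------------------------------------------------
# synthetic loci and junction generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticLoci:
    """Small two-chromosome reference with annotated IGH/BCL3-like features.

    ``features`` is a BED-like frame (chrom, start, end, name, feature_class,
    strand); ``sequences`` maps chromosome name to its nucleotide string.
    Coordinates are 1-based inclusive, and the centromeric side is the
    low-coordinate side on both chromosomes.
    """

    features: pd.DataFrame
    sequences: dict[str, str]
    # planted V(D)J breakpoint position per RSS spacer length
    vdj_breakpoints: dict[int, int] = None  # type: ignore[assignment]

    def feature(self, name: str) -> pd.Series:
        hit = self.features[self.features["name"] == name]
        if hit.empty:
            raise KeyError(f"no feature named {name}")
        return hit.iloc[0]

    def switch_regions(self) -> pd.DataFrame:
        sw = self.features[self.features["feature_class"] == "switch_region"]
        return sw.sort_values("start")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def generate_loci(seed: int = 0) -> SyntheticLoci:
    """Build the synthetic IGH (chr14) and BCL3-region (chr19) mini-loci.

    chr14 carries the seven switch regions in locus order plus one J and one
    D gene; canonical recombination-signal sequences (heptamer-spacer-
    nonamer, 12- and 23-base spacers) are embedded 12 bp downstream of the
    D-gene V(D)J breakpoint position.  chr19 carries CEACAM16 (with an
    intron-2 span), BCL3, CBLC (intron 9) and NECTIN2 in centromere-to-
    telomere order.
    """
    rng = np.random.default_rng(seed)
    chr14_len = 16000
    chr19_len = 12000
    seq14 = list(_random_seq(rng, chr14_len))
    seq19 = list(_random_seq(rng, chr19_len))

    rows = []
    # switch regions along the synthetic chr14, locus order from the J side:
    # IGHM closest to J/D genes (here: high coordinates), IGHA2 most distal.
    switch_names = ["IGHA2", "IGHG4", "IGHG2", "IGHA1", "IGHG1", "IGHG3", "IGHM"]
    pos = 1000
    for name in switch_names:
        rows.append(("chr14", pos, pos + 799, name, "switch_region", "-"))
        pos += 1500
    j_start = pos + 500
    rows.append(("chr14", j_start, j_start + 60, "IGHJ6", "J_gene", "-"))
    d_start = j_start + 600
    rows.append(("chr14", d_start, d_start + 40, "IGHD1_7", "D_gene", "-"))

    # embed plus-strand RSS motifs 12 bp after the D-gene start, so a V(D)J
    # breakpoint at the D-gene 5' boundary has the heptamer 12 bp away
    def plant_rss(seq: list[str], break_pos: int, spacer: int) -> None:
        motif = RSS_HEPTAMER + _random_seq(rng, spacer) + RSS_NONAMER
        start0 = (break_pos - 1) + 12  # 12 bases between breakpoint and heptamer
        seq[start0 : start0 + len(motif)] = list(motif)

    plant_rss(seq14, d_start, 12)
    plant_rss(seq14, d_start + 200, 23)
    rows.append(("chr14", d_start + 150, d_start + 260, "IGHD1_7_alt", "D_gene", "-"))

    # chr19: centromeric side = low coordinates; BCL3 sits telomeric of
    # CEACAM16, with CBLC and NECTIN2 further downstream
    rows.append(("chr19", 1000, 2999, "CEACAM16", "gene", "-"))
    rows.append(("chr19", 1600, 2200, "CEACAM16_intron2", "intron", "-"))
    rows.append(("chr19", 5000, 6999, "BCL3", "gene", "+"))
    rows.append(("chr19", 8000, 9499, "CBLC", "gene", "+"))
    rows.append(("chr19", 9000, 9300, "CBLC_intron9", "intron", "+"))
    rows.append(("chr19", 10500, 11500, "NECTIN2", "gene", "-"))

    features = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "feature_class", "strand"]
    )
    return SyntheticLoci(
        features=features,
        sequences={"chr14": "".join(seq14), "chr19": "".join(seq19)},
        vdj_breakpoints={12: d_start, 23: d_start + 200},
    )


@dataclass
class JunctionSimConfig:
    """Parameters for one simulated breakpoint junction."""

    mechanism: str  # "CSR" or "VDJ"
    switch_region: Optional[str] = None
    n_insert: int = 0
    microhomology: int = 0
    rss_spacer: int = 12
    derivative: str = "der14"
    flank: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("CSR", "VDJ"):
            raise ValueError("mechanism must be CSR or VDJ")
        if self.n_insert < 0 or self.microhomology < 0:
            raise ValueError("n_insert and microhomology must be nonnegative")
        if self.n_insert > 0 and self.microhomology > 0:
            raise ValueError("a junction cannot have both an insert and microhomology")
        if self.rss_spacer not in (12, 23):
            raise ValueError("rss_spacer must be 12 or 23")


@dataclass
class JunctionRecord:
    """A sequenced breakpoint junction between chr14 (IGH) and chr19 (BCL3)."""

    derivative: str
    pos14: int
    pos19: int
    junction_seq: str
    insert_len: int
    microhomology_len: int
    mechanism_call: str
    left_flank: str = ""
    right_flank: str = ""
    left_chrom: str = "chr14"
    right_chrom: str = "chr19"


def generate_junction(config: JunctionSimConfig, loci: SyntheticLoci) -> JunctionRecord:
    """Emit one junction with known mechanism, insert and breakpoints.

    CSR junctions break inside the configured IGH switch region and join a
    chr19 position centromeric (upstream) of BCL3:
    ``junction = chr14 flank + insert/microhomology + chr19 flank``.
    V(D)J junctions break at the D-gene boundary next to the embedded RSS:
    ``junction = chr19 flank + insert + chr14 flank`` so that the
    recombination-signal heptamer sits 12 bp from the junction point.
    """
    rng = np.random.default_rng(config.seed)
    f = config.flank
    seq14 = loci.sequences["chr14"]
    seq19 = loci.sequences["chr19"]
    bcl3 = loci.feature("BCL3")

    # chr19 breakpoint: uniform in the upstream (centromeric) region of BCL3
    pos19 = int(rng.integers(f + 1, int(bcl3["start"]) - f))

    if config.mechanism == "CSR":
        sw_name = config.switch_region or str(rng.choice(loci.switch_regions()["name"].to_numpy()))
        sw = loci.features[
            (loci.features["name"] == sw_name)
            & (loci.features["feature_class"] == "switch_region")
        ]
        if sw.empty:
            raise ValueError(f"unknown switch_region: {sw_name}")
        sw = sw.iloc[0]
        pos14 = int(rng.integers(int(sw["start"]), int(sw["end"]) + 1))
        # left flank: chr14 sequence ending at the breakpoint (inclusive)
        left = seq14[pos14 - f : pos14]
        if config.microhomology > 0:
            m = config.microhomology
            # the chr19 reference flank starts with the shared bases, which
            # appear once in the junction
            right_ref = left[-m:] + seq19[pos19 - 1 + m : pos19 - 1 + f]
            junction = left + right_ref[m:]
            insert = ""
        else:
            right_ref = seq19[pos19 - 1 : pos19 - 1 + f]
            insert = _guarded_insert(rng, config.n_insert, left, right_ref)
            junction = left + insert + right_ref
        return JunctionRecord(
            derivative=config.derivative,
            pos14=pos14,
            pos19=pos19,
            junction_seq=junction,
            insert_len=len(insert) if config.microhomology == 0 else 0,
            microhomology_len=config.microhomology,
            mechanism_call="CSR",
            left_flank=left,
            right_flank=right_ref if config.microhomology > 0 else seq19[pos19 - 1 : pos19 - 1 + f],
            left_chrom="chr14",
            right_chrom="chr19",
        )

    # V(D)J: break at the planted D-gene anchor; the RSS is embedded 12 bp
    # into the retained chr14 side, so the junction is
    # chr19-flank + insert + chr14-flank
    pos14 = int(loci.vdj_breakpoints[config.rss_spacer])
    left = seq19[pos19 - f : pos19]
    right = seq14[pos14 - 1 : pos14 - 1 + f]
    insert = _guarded_insert(rng, max(1, config.n_insert), left, right)
    junction = left + insert + right
    return JunctionRecord(
        derivative=config.derivative,
        pos14=pos14,
        pos19=pos19,
        junction_seq=junction,
        insert_len=len(insert),
        microhomology_len=0,
        mechanism_call="VDJ",
        left_flank=left,
        right_flank=right,
        left_chrom="chr19",
        right_chrom="chr14",
    )


def _guarded_insert(rng: np.random.Generator, n: int, left: str, right: str) -> str:
    """Untemplated insert that cannot extend either flank match."""
    if n == 0:
        return ""
    bases = list("ACGT")
    ins = list(_random_seq(rng, n))
    # first base must differ from the base the right flank starts with and
    # last base from the base the left flank ends with, so flank matches
    # stay exactly at the planted lengths
    while ins[0] == right[0]:
        ins[0] = str(rng.choice(bases))
    while ins[-1] == left[-1]:
        ins[-1] = str(rng.choice(bases))
    return "".join(ins)
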