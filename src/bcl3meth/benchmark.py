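"""Reference simulation benchmarks used by the test suite and the
reproduction script.

:func:`classifier_benchmark` runs the full classifier pipeline on the
standard synthetic cohort surrogate (80 translocation-positive cases versus
150 pooled other-CLL controls, ~1985 planted differentially methylated CpGs
at a 0.35 beta-scale effect, beta noise at concentration 50, tumor purity
uniform on [0.6, 1.0]) for a set of seeds and collects the held-out
metrics.  :func:`dmc_benchmark` measures planted-DMC recovery at the
standard filters over repeated simulations, and :func:`cnv_benchmark`
measures recovery of a planted chromosome-12 gain.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import diffmeth, synth
from .classifier import ClassifierConfig, Metrics, labels_from_sheet, train_classifier

#: conditions of the standard classifier surrogate cohort
CLASSIFIER_COHORT = dict(
    n_cases=80,
    n_controls=75,
    control_groups=("CLL_U", "CLL_IGTRANS"),
    n_cpgs=20000,
    n_hypo=1960,
    n_hyper=25,
    delta_beta=0.35,
    precision=50.0,
    purity_range=(0.6, 1.0),
)


def classifier_benchmark(
    seeds: Sequence[int], config: Optional[ClassifierConfig] = None
) -> list[Metrics]:
    """Held-out metrics of the full pipeline, one cohort+model per seed."""
    out: list[Metrics] = []
    for seed in seeds:
        cfg = synth.CohortConfig(seed=synth.child_seed(seed, 1), **CLASSIFIER_COHORT)
        ann = synth.generate_annotation(cfg.n_cpgs, seed=synth.child_seed(seed, 0))
        beta, sheet, _ = synth.generate_cohort(cfg, ann)
        labels = labels_from_sheet(sheet)
        clf_config = config or ClassifierConfig(seed=seed)
        if config is None:
            clf_config = ClassifierConfig(seed=seed)
        _, metrics = train_classifier(beta, labels, clf_config)
        out.append(metrics)
    return out


def dmc_benchmark(
    n_sims: int = 50,
    seed: int = 0,
    n_cpgs: int = 2000,
    n_hypo: int = 196,
    n_hyper: int = 4,
) -> pd.DataFrame:
    """Planted-DMC recovery at FDR < 0.01 and |delta beta| > 0.3.

    Cohorts use 80 cases / 32 controls at a planted effect of 0.35 with
    high-concentration beta noise and purity 1, the regime of the supervised
    discovery analysis.  Returns per-simulation sensitivity, observed false
    discovery proportion, and the call fraction on a matched null cohort.
    """
    rows = []
    for i in range(n_sims):
        s = synth.child_seed(seed, 100 + i)
        ann = synth.generate_annotation(n_cpgs, seed=s)
        cfg = synth.CohortConfig(
            n_cases=80, n_controls=32, control_groups=("CLL_U",),
            n_cpgs=n_cpgs, n_hypo=n_hypo, n_hyper=n_hyper,
            delta_beta=0.35, precision=100.0, purity_range=(1.0, 1.0),
            seed=synth.child_seed(s, 1),
        )
        beta, sheet, truth = synth.generate_cohort(cfg, ann)
        cases = sheet.loc[sheet["group"] == "BCL3", "sample_id"].tolist()
        controls = sheet.loc[sheet["group"] == "CLL_U", "sample_id"].tolist()
        table = diffmeth.dmc_analysis(beta, cases, controls)
        called = set(table.index[table["call"] != "none"])
        true_set = set(truth["cpg_id"])
        tp = len(called & true_set)
        sens = tp / len(true_set)
        fdp = (len(called) - tp) / max(1, len(called))

        # matched null: no planted effect (both groups draw from the baseline)
        null_cfg = synth.CohortConfig(
            n_cases=80, n_controls=32, control_groups=("CLL_U",),
            n_cpgs=n_cpgs, n_hypo=0, n_hyper=0,
            delta_beta=0.35, precision=100.0, purity_range=(1.0, 1.0),
            seed=synth.child_seed(s, 2),
        )
        null_beta, null_sheet, _ = synth.generate_cohort(null_cfg, ann)
        n_cases_ids = null_sheet.loc[null_sheet["group"] == "BCL3", "sample_id"].tolist()
        n_ctrl_ids = null_sheet.loc[null_sheet["group"] == "CLL_U", "sample_id"].tolist()
        null_table = diffmeth.dmc_analysis(null_beta, n_cases_ids, n_ctrl_ids)
        null_rate = float((null_table["call"] != "none").mean())
        rows.append({"sensitivity": sens, "fdp": fdp, "null_call_rate": null_rate})
    return pd.DataFrame(rows)


def cnv_benchmark(
    n_sims: int = 100,
    seed: int = 0,
    n_probes: int = 2000,
    shift: float = 0.15,
    noise_sd: float = 0.03,
) -> pd.DataFrame:
    """Recovery of a planted chromosome-12 gain against a reference panel."""
    rows = []
    for i in range(n_sims):
        s = synth.child_seed(seed, 200 + i)
        ann = synth.generate_annotation(n_probes, seed=s)
        samples = ["tumor"] + [f"ref{j}" for j in range(5)]
        inten = synth.generate_intensity(ann, samples[1:], [], noise_sd=noise_sd,
                                         seed=synth.child_seed(s, 1))
        tumor = synth.generate_intensity(ann, ["tumor"], [("chr12", shift)],
                                         noise_sd=noise_sd, seed=synth.child_seed(s, 2))
        ratios = cnv_mod.reference_ratios(tumor["tumor"], inten)
        calls = cnv_mod.segment_and_call(ratios, ann)
        gains_chr12 = calls[(calls["chromosome"] == "chr12") & (calls["state"] == "gain")]
        off_target = calls[(calls["chromosome"] != "chr12") & (calls["state"] != "neutral")]
        rows.append(
            {
                "n_gain_chr12": len(gains_chr12),
                "n_calls_elsewhere": len(off_target),
                "exact_recovery": len(gains_chr12) == 1 and len(off_target) == 0,
            }
        )
    return pd.DataFrame(rows)


def junction_benchmark(n_csr: int = 100, n_vdj: int = 100, seed: int = 0) -> pd.DataFrame:
    """Mechanism recovery plus exact insert / RSS-distance round-trips."""
    from . import junctions as jx

    loci = synth.generate_loci(seed=synth.child_seed(seed, 0))
    inserts = [0, 6, 11] + list(range(1, 31))
    rows = []
    for i in range(n_csr + n_vdj):
        mech = "CSR" if i < n_csr else "VDJ"
        planted = inserts[i % len(inserts)] if mech == "CSR" else max(1, inserts[i % len(inserts)])
        cfg = synth.JunctionSimConfig(
            mechanism=mech, n_insert=planted,
            rss_spacer=12 if i % 2 == 0 else 23,
            seed=synth.child_seed(seed, 300 + i),
        )
        rec = synth.generate_junction(cfg, loci)
        ins, mh = jx.junction_inserts(rec.junction_seq, rec.left_flank, rec.right_flank)
        call = jx.infer_mechanism(rec, loci)
        rss_distance = np.nan
        if mech == "VDJ":
            boundary = len(rec.left_flank) + ins
            hits = [h for h in jx.detect_rss(rec.junction_seq) if h.position - 1 >= boundary]
            if hits:
                rss_distance = hits[0].position - 1 - boundary
        rows.append(
            {
                "mechanism_true": rec.mechanism_call,
                "mechanism_called": call,
                "insert_true": rec.insert_len,
                "insert_recovered": ins,
                "microhomology_recovered": mh,
                "rss_distance": rss_distance,
            }
        )
    return pd.DataFrame(rows)
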