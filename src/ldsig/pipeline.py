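"""End-to-end orchestration with config, logging and a reproducible report.

:func:`run_all` composes every stage on synthetic inputs (or user-supplied
files): per-tissue strain-baseline contrasts -> systemic signature and its
negative control -> graded dose/time gene lists -> dose-response
nonlinearity classes -> ortholog mapping -> cohort survival association with
COA refinement -> direction concordance against a directed human comparator
set -> micronucleus statistics -> printed-table fixture summaries.  The
report embeds the seed and a hash of the full config so a run can be
reproduced from its own report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, mn as mn_mod
from .concordance import concordance, overlap_test
from .data_io import GeneSet, load_fixture_table, summarize_coa_fixture
from .de import classify_calls, classify_dose_response, contrast, gene_list
from .orthologs import map_signature
from .signature import derive_systemic_signature, negative_control_signature
from .survival import logrank_test, median_split, signature_score, survival_pipeline
from .synthetic import SynthConfig, gen_cohort, gen_mn_counts, gen_mouse_study, gen_ortholog_table

logger = logging.getLogger("ldsig")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Every threshold of the pipeline, with its standard default."""

    seed: int = 0
    synth: SynthConfig | None = None
    # graded list criteria
    p_cut_hd: float = 0.01
    p_cut_ld: float = 0.1
    p_cut_baseline: float = 0.05
    fc_cut: float = de.FC_CUT
    # systemic signature
    signature_p_cut: float = 0.05
    signature_fc_cut: float = de.FC_CUT
    # ortholog mapping loss
    ortholog_drop_fraction: float = 0.28
    # survival association
    normalization: str = "zscore"
    coa_alpha: float = 0.01
    # micronucleus statistics
    dunnett_n_mc: int = 100_000

    def __post_init__(self) -> None:
        if self.synth is None:
            self.synth = SynthConfig(seed=self.seed)
        elif isinstance(self.synth, dict):
            self.synth = SynthConfig(**self.synth)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _fixture_checks() -> dict:
    t2 = summarize_coa_fixture(load_fixture_table("table2_baseline_coa"))
    t3 = summarize_coa_fixture(load_fixture_table("table3_ld1month_coa"))
    t1 = load_fixture_table("table1_early_ld_overlaps")
    t1_fracs = {
        row.gene_function: int(round(100 * row.overlap / row.list_size))
        for row in t1.itertuples()
    }
    t4 = load_fixture_table("table4_thresholded")
    classes = []
    for row in t4.itertuples():
        fc = {
            "ld_sensitive": float(row.ld_sensitive),
            "hd_sensitive": float(row.hd_sensitive),
            "ld_resistant": 0.0 if row.ld_resistant == "ns" else float(row.ld_resistant),
            "hd_resistant": float(row.hd_resistant),
        }
        sig = {k: not (k == "ld_resistant" and row.ld_resistant == "ns") for k in fc}
        classes.append(classify_calls(fc, sig))
    hd_s = t4["hd_sensitive"].astype(float).to_numpy()
    hd_r = t4["hd_resistant"].astype(float).to_numpy()
    ld_s = t4["ld_sensitive"].astype(float).to_numpy()
    return {
        "table2_summary": t2,
        "table3_summary": t3,
        "table1_fractions": t1_fracs,
        "table4_n_thresholded": int(sum(c == "thresholded" for c in classes)),
        "table4_n_rows": int(len(classes)),
        "magnitude_p_hd_resistant_vs_hd_sensitive": de.magnitude_comparison(hd_r, hd_s),
        "magnitude_p_hd_resistant_vs_ld_sensitive": de.magnitude_comparison(hd_r, ld_s),
    }


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Run every pipeline stage on synthetic inputs; return the report bundle.

    Deterministic given ``config.seed``.  With ``out_dir`` the main tables
    are written as TSV and the numeric summary as JSON.
    """
    synth = config.synth
    report: dict = {"seed": config.seed, "config_hash": config.digest(),
                    "config": config.to_dict()}

    stage = "synthesis"
    try:
        study, truth = gen_mouse_study(synth)

        stage = "baseline contrasts"
        sham = {"dose": "sham"}
        blood = contrast(study, {"tissue": "blood", "strain": "sensitive", **sham},
                         {"tissue": "blood", "strain": "resistant", **sham})
        mg = contrast(study, {"tissue": "mammary", "strain": "sensitive", **sham},
                      {"tissue": "mammary", "strain": "resistant", **sham})

        stage = "systemic signature"
        sig = derive_systemic_signature(
            blood, mg, p_cut=config.signature_p_cut, fc_cut=config.signature_fc_cut
        )
        control_genes = negative_control_signature(blood, mg, k=len(sig.genes) or synth.n_baseline_signature)
        planted = set(truth.baseline_signature)
        sensitivity = (
            len(planted & set(sig.symbols)) / len(planted) if planted else float("nan")
        )
        report["systemic_signature"] = {
            "n_genes": len(sig.genes),
            "r_squared": sig.r_squared,
            "sensitivity_vs_planted": sensitivity,
            "n_control_genes": len(control_genes),
        }

        stage = "dose/time gene lists"
        counts = {}
        per_condition = {}
        for strain in ("sensitive", "resistant"):
            for dose in ("LD", "HD"):
                for time in ("early", "late"):
                    c = contrast(
                        study,
                        {"tissue": "mammary", "strain": strain, "dose": dose, "time": time},
                        {"tissue": "mammary", "strain": strain, "dose": "sham", "time": time},
                    )
                    gl = gene_list(
                        c, dose,
                        p_cutoff=config.p_cut_hd if dose == "HD" else config.p_cut_ld,
                        fc_cutoff=config.fc_cut,
                    )
                    counts[f"{strain}_{dose}_{time}"] = {
                        "up": len(gl.up), "down": len(gl.down)
                    }
                    per_condition[(strain, dose, time)] = (c, gl)
        report["gene_list_counts"] = counts

        stage = "dose-response classification"
        classes = classify_dose_response(
            {
                "ld_sensitive": per_condition[("sensitive", "LD", "early")][0],
                "hd_sensitive": per_condition[("sensitive", "HD", "early")][0],
                "ld_resistant": per_condition[("resistant", "LD", "early")][0],
                "hd_resistant": per_condition[("resistant", "HD", "early")][0],
            }
        )
        report["dose_response_counts"] = (
            classes["dose_class"].value_counts().to_dict()
        )

        stage = "ortholog mapping"
        table = gen_ortholog_table(
            study.gene_ids, config.ortholog_drop_fraction, seed=config.seed
        )
        mapped = map_signature(sig.symbols, table, directions=sig.directions())
        report["orthologs"] = {
            "n_mouse": len(sig.genes),
            "n_human": len(mapped.human_genes),
            "n_dropped": len(mapped.dropped),
        }

        stage = "survival association"
        ctrl_mapped = map_signature(control_genes, table)
        if not mapped.human_genes:
            logger.warning("run_all: empty mapped signature; survival stage skipped")
            cohort = surv = None
        else:
            cohort, cohort_truth = gen_cohort(
                synth, mapped.human_genes, background_genes=ctrl_mapped.human_genes
            )
            surv = survival_pipeline(
                cohort, sig.symbols, table,
                normalization=config.normalization, coa_alpha=config.coa_alpha,
            )
        ctrl_report = None
        if cohort is not None and ctrl_mapped.human_genes:
            ctrl_score = signature_score(
                cohort, ctrl_mapped.human_genes, normalization=config.normalization
            )
            ctrl_split = median_split(ctrl_score)
            ctrl_lr = logrank_test(
                (cohort.time[ctrl_split.above], cohort.event[ctrl_split.above]),
                (cohort.time[~ctrl_split.above], cohort.event[~ctrl_split.above]),
            )
            ctrl_report = {"p_value": ctrl_lr.p_value, "chi_sq": ctrl_lr.chi_sq}
        report["survival"] = None if surv is None else {
            "logrank_p": surv["logrank"].p_value,
            "logrank_chi_sq": surv["logrank"].chi_sq,
            "n_coa": len(surv["coa"].coa_genes),
            "n_inverse": len(surv["coa"].inverse_genes),
            "directed_subset_p": (
                surv["directed_subset"]["logrank"].p_value
                if surv["directed_subset"] else None
            ),
            "negative_control": ctrl_report,
            "n_above": surv["split"].n_above,
            "n_below": surv["split"].n_below,
        }

        stage = "concordance"
        sens_dirs = per_condition[("sensitive", "LD", "late")][1].directions()
        res_dirs = per_condition[("resistant", "LD", "late")][1].directions()
        human_truth = truth.ld_response.get(("sensitive", "LD", "late"), {})
        if human_truth:
            human_set = GeneSet(
                name="human_biomarkers",
                members={g.upper() for g in human_truth},
                directions={g.upper(): s for g, s in human_truth.items()},
            )
            calls = concordance(sens_dirs, res_dirs, human_set)
            report["concordance"] = {
                "n_genes": int(len(calls)),
                "n_concordant": int(calls["concordant"].sum()),
            }
        else:
            calls = None
            report["concordance"] = None

        stage = "micronucleus statistics"
        records = gen_mn_counts(synth)
        freqs = mn_mod.mn_frequencies(records)
        mn_report = {}
        for cc in sorted(freqs["cell_class"].unique()):
            sub = freqs[(freqs["cell_class"] == cc) & (freqs["dose"] == "sham")]
            bc = mn_mod.baseline_compare(
                sub.loc[sub["strain"] == "sensitive", "freq"],
                sub.loc[sub["strain"] == "resistant", "freq"],
            )
            mn_report[cc] = {"baseline": bc}
        # Dunnett per strain and cell class at the late time point
        for cc in sorted(freqs["cell_class"].unique()):
            for strain in ("sensitive", "resistant"):
                sub = freqs[
                    (freqs["cell_class"] == cc)
                    & (freqs["strain"] == strain)
                    & (freqs["time_point"] == "late")
                ]
                doses = [d for d in ("LD", "HD", "LD+HD") if (sub["dose"] == d).any()]
                adj = mn_mod.dunnett_vs_control(
                    [sub.loc[sub["dose"] == d, "freq"].to_numpy() for d in doses],
                    sub.loc[sub["dose"] == "sham", "freq"].to_numpy(),
                    n_mc=config.dunnett_n_mc,
                    seed=config.seed,
                )
                mn_report[cc][f"dunnett_late_{strain}"] = dict(
                    zip(doses, [float(x) for x in adj])
                )
        report["micronucleus"] = mn_report

        stage = "fixture summaries"
        report["fixtures"] = _fixture_checks()
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted in stage {stage!r} (seed={config.seed}, "
            f"config_hash={config.digest()}): {exc}"
        ) from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        sig.genes.to_csv(out / "systemic_signature.tsv", sep="\t", index=False)
        classes.to_csv(out / "dose_response_classes.tsv", sep="\t", index=False)
        if surv is not None:
            surv["coa"].table.to_csv(out / "coa_table.tsv", sep="\t", index=False)
        if calls is not None:
            calls.to_csv(out / "concordance.tsv", sep="\t", index=False)
        freqs.to_csv(out / "mn_frequencies.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        logger.info("run_all: report written to %s", out)

    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if isinstance(obj, float) and math.isnan(obj) else float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
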