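"""End-to-end orchestration of the analysis stages.

``run_full`` chains the stages in their natural order on file inputs —
length filter, gap-column trimming, representative clustering, diversity
coverage, rate harmonization (Q10, control normalization, assay
correction), rate summaries, the rate-ratio-vs-identity landscape, the
identity-thresholded cross-validation benchmark, per-form prediction of
uncharacterized variants, and the position-association analysis — and
writes each stage's output as TSV/JSON into an output directory.  Every
output is stamped with a hash of the configuration and the master seed
so runs are attributable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics, seqspace
from .association import AssociationConfig, fit_position_association, map_alignment_to_reference
from .predict import ModelSpec, loo_crossval, one_hot_encode, predict_all

log = logging.getLogger("rubiscope")


@dataclass
class PipelineConfig:
    """Paths, constants and the master seed for a full run.

    The constants default to the study values: Q10 = 2.2 toward 30 degC,
    gap-column cutoff 0.95, length bounds 300-700 aa, representative
    clustering at 90% identity (selection clustering at 80%), and the
    pinned SVR defaults.  ``correction_factor`` overrides the fitted
    assay correction when no paired table is available.
    """

    alignment: str = ""
    metadata: str | None = None
    rates: str | None = None
    pairs: str | None = None
    outdir: str = "rubiscope_out"

    q10: float = kinetics.DEFAULT_Q10
    t_target: float = kinetics.DEFAULT_T_TARGET
    gap_trim: float = 0.95
    min_len: int = 300
    max_len: int = 700
    cluster_threshold: float = 0.9
    selection_threshold: float = 0.8
    coverage_thresholds: list[float] = field(
        default_factory=lambda: list(seqspace.DEFAULT_COVERAGE_THRESHOLDS)
    )
    cv_thresholds: list[float] = field(
        default_factory=lambda: [0.5, 0.6, 0.7, 0.8, 0.9]
    )
    control_id: str | None = None
    control_reference: float | None = None
    correction_factor: float | None = None
    model: str = "svr_rbf"
    lam: float = 14.0
    association_iterations: int = 100
    association_depth: int = 3
    association_forms: list[str] | None = None
    reference_id: str | None = None
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _stamp(cfg: PipelineConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed}


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_full(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory results keyed by stage name.

    Stage failures raise with the stage name prepended.  Outputs land in
    ``cfg.outdir`` (TSV with a provenance comment line, JSON for
    scalars).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": cfg}
    stage = "load"
    try:
        aln = seqspace.read_alignment(cfg.alignment, metadata=cfg.metadata)
        rates = kinetics.read_rates(cfg.rates) if cfg.rates else None

        stage = "length_filter"
        kept, rejected = seqspace.length_filter(aln, cfg.min_len, cfg.max_len)
        aln = aln.subset_ids(kept)
        _write_tsv(rejected, out / "length_rejected.tsv", cfg)
        results["length_filter"] = {"kept": len(kept), "rejected": len(rejected)}

        stage = "trim"
        aln = seqspace.trim_gap_columns(aln, cfg.gap_trim)
        results["trim"] = {"n_columns": aln.length}

        stage = "cluster"
        clusters = seqspace.greedy_cluster(aln, cfg.cluster_threshold)
        _write_tsv(clusters.to_frame(), out / "clusters.tsv", cfg)
        results["cluster"] = clusters

        stage = "coverage"
        reps = aln.subset_ids(clusters.centroid_ids)
        char_ids = [s for s, c in zip(aln.ids, aln.characterized) if c]
        characterized = aln.subset_ids(char_ids)
        curve = seqspace.diversity_coverage(reps, characterized, cfg.coverage_thresholds)
        _write_tsv(curve.to_frame(), out / "coverage.tsv", cfg)
        results["coverage"] = curve

        harmonized = None
        if rates is not None:
            stage = "harmonize"
            rates = kinetics.q10_correct(rates, cfg.t_target, cfg.q10)
            if cfg.control_id and cfg.control_reference:
                rates, missing = kinetics.normalize_to_control(
                    rates, cfg.control_id, cfg.control_reference
                )
                if len(missing):
                    _write_tsv(missing, out / "unnormalized_batches.tsv", cfg)
            if cfg.pairs:
                pair_df = pd.read_csv(cfg.pairs)
                fit = kinetics.fit_assay_correction(
                    pair_df[["k_coupled", "k_direct"]].to_numpy()
                )
            elif cfg.correction_factor:
                fit = cfg.correction_factor
            else:
                fit = None
            if fit is not None:
                coupled = rates["assay"] == "coupled"
                corrected = kinetics.apply_correction(rates[coupled], fit)
                rates = pd.concat([corrected, rates[~coupled]], ignore_index=True)
                if isinstance(fit, kinetics.CorrectionFit):
                    (out / "correction_fit.json").write_text(
                        json.dumps({**fit.to_dict(), **_stamp(cfg)}, indent=2)
                    )
            results["correction_fit"] = fit
            if cfg.control_id:
                rates = rates[rates["variant_id"] != cfg.control_id]
            kinetics.write_rates(rates, out / "harmonized_rates.csv")
            harmonized = kinetics.collapse_replicates(rates)

            stage = "summarize"
            forms = dict(zip(aln.ids, aln.form))
            summaries = kinetics.summarize_rates(rates, forms=forms, group_by="form")
            summaries += kinetics.summarize_rates(rates, group_by="all")
            sum_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
            _write_tsv(sum_df, out / "rate_summaries.tsv", cfg)
            results["summaries"] = summaries

            stage = "ratio_vs_identity"
            measured = [v for v in harmonized.index if v in set(aln.ids)]
            ratio = kinetics.rate_ratio_vs_identity(
                rates[rates["variant_id"].isin(measured)], aln
            )
            _write_tsv(ratio.to_frame(), out / "ratio_vs_identity.tsv", cfg)
            results["ratio_vs_identity"] = ratio

            stage = "crossval"
            char = aln.subset_ids([v for v in char_ids if v in set(measured)])
            ln_rates = {v: float(np.log(harmonized[v])) for v in char.ids}
            spec = ModelSpec(kind=cfg.model, lam=cfg.lam)
            cv = loo_crossval(char, ln_rates, spec, thresholds=cfg.cv_thresholds)
            _write_tsv(cv.to_frame(), out / "crossval.tsv", cfg)
            results["crossval"] = cv

            stage = "predict"
            preds = predict_all(aln, ln_rates, spec)
            _write_tsv(preds.predictions, out / "predictions.tsv", cfg)
            results["predictions"] = preds

            stage = "associate"
            scope = cfg.association_forms
            idx = [
                i
                for i, v in enumerate(char.ids)
                if scope is None or char.form[i] in scope
            ]
            if len(idx) >= 20:
                sub = char.subset(idx)
                enc = one_hot_encode(sub)
                y = np.array([ln_rates[v] for v in sub.ids])
                ref_map = (
                    map_alignment_to_reference(sub, cfg.reference_id)
                    if cfg.reference_id and cfg.reference_id in sub.ids
                    else None
                )
                assoc = fit_position_association(
                    enc,
                    y,
                    AssociationConfig(
                        n_iterations=cfg.association_iterations,
                        max_depth=cfg.association_depth,
                        seed=cfg.seed,
                        forms=tuple(scope) if scope else None,
                    ),
                    reference_map=ref_map,
                )
                _write_tsv(assoc.ranked(), out / "association.tsv", cfg)
                results["association"] = assoc
            else:
                log.warning("associate: fewer than 20 in-scope variants, skipped")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "run.json").write_text(
        json.dumps(
            {
                **_stamp(cfg),
                "stages": sorted(k for k in results if k != "config"),
            },
            indent=2,
        )
    )
    results["harmonized"] = harmonized
    return results
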