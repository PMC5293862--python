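"""End-to-end orchestration: simulate -> qc -> deisotope -> stats ->
aggregate -> annotate, as a configured, logged, reproducible run.

Positive and negative ion modes are separate runs (peak tables from the
two ESI modes never mix). Every artifact is written into the run
directory; no stage mutates its inputs. Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import deisotope as di
from . import qc as qcmod
from . import simulate as sim
from . import stats as st
from .annotate import annotate_peaks
from .msp import write_msp
from .peaks import read_peak_table, read_sample_meta, write_peak_table, write_sample_meta

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("grassmet")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults are the pipeline's operating points: 20 ppm mass windows,
    +/-0.2 min RT tolerance, r > 0.9 isotope/co-elution correlation,
    [M]/[M+1] and [M+1]/[M+2] ratios > 2, batch-residual and invariance
    filters at alpha 0.05, differential FDR 0.01, intensity gate 1e5 with
    top-50 ranking.
    """

    # stage toggles
    simulate: bool = True
    qc: bool = True
    deisotope: bool = True
    stats: bool = True
    aggregate: bool = True
    annotate: bool = True

    # inputs (used when simulate is off)
    peak_table: str | None = None
    sample_meta: str | None = None

    # simulation
    seed: int = 0
    preset: str = "default"        # default | full
    noise_cv: float = 0.2

    # qc
    ppm_tol: float = 20.0
    rt_tol: float = 0.2
    alpha_batch: float = 0.05
    alpha_invariance: float = 0.05
    cv_trigger: float = 0.2
    z_threshold: float = 3.0
    cv_threshold: float = 0.3

    # deisotope
    r_min: float = 0.9
    ratio_min: float = 2.0

    # stats
    intensity_min: float = 1e5
    top_k: int = 50
    fdr_alpha: float = 0.01

    # aggregate: list of {mz, ppm, rt_min, rt_max} mappings
    aggregate_targets: list[dict] = field(default_factory=list)

    # annotate
    annotate_top_only: bool = True
    coelute_rt_tol: float = 0.05

    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _design(config: RunConfig) -> sim.DesignSpec:
    if config.preset == "full":
        return sim.full_design(config.seed)
    if config.preset == "default":
        return sim.default_design(config.seed)
    raise ValueError(f"unknown preset {config.preset!r}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in fixed order; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    config.to_yaml(out / "config.yaml")
    stage_counts: list[dict] = []

    try:
        # ---- inputs -----------------------------------------------------
        truth = None
        if config.simulate:
            spec = _design(config)
            meta = sim.generate_design(spec)
            truth = sim.simulate_truth(spec)
            matrix, annot = sim.render_intensity_matrix(
                truth, meta, noise_cv=config.noise_cv, seed=config.seed)
            write_sample_meta(out / "sample_meta.tsv", meta)
            write_peak_table(out / "peak_table_raw.tsv", matrix, annot)
            spectra = sim.render_pseudo_spectra(truth)
            (out / "truth_spectra.msp").write_text(write_msp(spectra))
            log.info("simulate: %d peaks x %d samples", *matrix.shape)
        else:
            if not config.peak_table or not config.sample_meta:
                raise FileNotFoundError(
                    "simulate disabled: peak_table and sample_meta required")
            matrix, annot = read_peak_table(config.peak_table)
            meta = read_sample_meta(config.sample_meta)
            log.info("loaded: %d peaks x %d samples", *matrix.shape)
        stage_counts.append({"stage": "input", "peaks": len(matrix)})

        # ---- qc ---------------------------------------------------------
        if config.qc:
            matrix, annot, qc_log, cv_report = qcmod.run_qc(
                matrix, annot, meta,
                ppm_tol=config.ppm_tol, rt_tol=config.rt_tol,
                alpha_batch=config.alpha_batch,
                alpha_invariance=config.alpha_invariance,
                cv_trigger=config.cv_trigger, z_threshold=config.z_threshold,
                cv_threshold=config.cv_threshold)
            for s in qc_log.stages:
                log.info("qc/%s: %d -> %d (%s)", s["stage"], s["peaks_in"],
                         s["peaks_out"], s["criterion"])
                stage_counts.append({"stage": f"qc/{s['stage']}",
                                     "peaks": s["peaks_out"]})
            with open(out / "qc_report.json", "w") as fh:
                json.dump({
                    "stages": qc_log.stages,
                    "cv_fraction_below_threshold": cv_report.fraction_below,
                    "cv_threshold": cv_report.threshold,
                }, fh, indent=2)
            write_peak_table(out / "peak_table_qc.tsv", matrix, annot)
        else:
            log.warning("qc disabled: downstream stages run on the raw table")

        # ---- deisotope --------------------------------------------------
        if config.deisotope:
            groups = di.find_isotope_groups(
                matrix, annot, ppm_tol=config.ppm_tol, rt_tol=config.rt_tol,
                r_min=config.r_min, ratio_min=config.ratio_min)
            n0 = len(matrix)
            matrix = di.deisotope(matrix, groups)
            annot = annot[annot["peak_id"].isin(matrix.index)].reset_index(drop=True)
            di.groups_to_frame(groups).to_csv(out / "isotope_groups.csv", index=False)
            log.info("deisotope: %d -> %d (%d groups)", n0, len(matrix), len(groups))
            stage_counts.append({"stage": "deisotope", "peaks": len(matrix)})
            write_peak_table(out / "peak_table_deisotoped.tsv", matrix, annot)

        # ---- stats ------------------------------------------------------
        ranked = None
        if config.stats:
            gmat, gpop = st.median_by_genotype(matrix, meta)
            result = st.moderated_population_test(gmat, gpop)
            n_sig = int((result["p_adj"] < config.fdr_alpha).sum())
            log.info("stats: %d/%d peaks differential at FDR < %g",
                     n_sig, len(result), config.fdr_alpha)
            ranked = st.rank_top_peaks(result, config.intensity_min, config.top_k)
            ranked.to_csv(out / "top_peaks.csv")
            result.to_csv(out / "diff_result.csv")
            profiles = st.population_profiles(matrix, meta)
            tree, _, _ = st.upgma(profiles)
            tree.write(str(out / "populations.nwk"))
            profiles.to_csv(out / "population_profiles.csv")

        # ---- aggregate --------------------------------------------------
        if config.aggregate and config.aggregate_targets:
            agg_out = []
            for tgt in config.aggregate_targets:
                rt_range = None
                if tgt.get("rt_min") is not None and tgt.get("rt_max") is not None:
                    rt_range = (tgt["rt_min"], tgt["rt_max"])
                res = st.aggregate_isomeric_peaks(
                    matrix, annot, tgt["mz"], tgt.get("ppm", 10.0),
                    rt_range, meta)
                agg_out.append({
                    "target_mz": res.target_mz,
                    "ppm_window": res.ppm_window,
                    "n_members": len(res.member_peaks),
                    "member_peaks": res.member_peaks,
                    "f_statistic": res.f_statistic,
                    "p_value": res.p_value,
                    "notice": res.notice,
                })
                res.aggregate.rename("aggregate").to_csv(
                    out / f"aggregate_{res.target_mz:.4f}.csv")
            with open(out / "aggregate_ftests.json", "w") as fh:
                json.dump(agg_out, fh, indent=2)

        # ---- annotate ---------------------------------------------------
        if config.annotate:
            targets = list(ranked.index) if (ranked is not None and
                                             config.annotate_top_only) else None
            table = annotate_peaks(
                matrix, annot, peak_ids=targets,
                adduct="[M+H]+" if meta["ion_mode"].iloc[0] == "positive"
                else "[M-H]-",
                ppm_tol=config.ppm_tol, r_min=config.r_min,
                rt_tol=config.coelute_rt_tol)
            table.to_csv(out / "annotations.csv", index=False)
            log.info("annotate: %d/%d peaks named",
                     int(table["name"].notna().sum()), len(table))

        with open(out / "peak_counts.json", "w") as fh:
            json.dump(stage_counts, fh, indent=2)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
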