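"""Synthetic multi-batch LC-MS peak tables with known ground truth.

Emulates a population-scale metabotyping survey: N populations with a range
of genotypes per population and clonal replicates per genotype, assayed in
randomized batches with bulk control samples, per-batch intensity
location/scale effects, retention-time drift that splits closely eluting
isomers into extra detected peak rows, 13C isotope envelopes, and
population-specific metabolite presence/absence.

The generator is the test bed for every downstream stage: it returns a
:class:`TruthSet` recording which metabolites are truly differential, which
cells were injected as outliers, and which peak rows are isotope partners,
so that recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .chem import (
    AGLYCONE_LIBRARY,
    MOIETY_LIBRARY,
    P_13C,
    C13_C12_SPACING,
    adduct_mz,
    monoisotopic_mass,
)
from .msp import Spectrum
from .peaks import format_peak_id

__all__ = [
    "DesignSpec",
    "MetaboliteConfig",
    "TrueMetabolite",
    "BatchEffectSpec",
    "TruthSet",
    "ConfigError",
    "generate_design",
    "simulate_truth",
    "render_intensity_matrix",
    "render_pseudo_spectra",
    "default_design",
    "full_design",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Experimental design of the survey.

    ``genotypes_per_population`` is an inclusive (lo, hi) range sampled per
    population; ``total_genotypes`` optionally pins the overall genotype
    count (counts are nudged within the range until the total matches).
    """

    n_populations: int = 10
    genotypes_per_population: tuple[int, int] = (6, 6)
    n_replicates: int = 5
    n_batches: int = 12
    controls_per_batch: int = 2
    ion_mode: str = "positive"
    seed: int = 0
    total_genotypes: int | None = None

    def validate(self) -> None:
        for name in ("n_populations", "n_replicates", "n_batches"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        lo, hi = self.genotypes_per_population
        if not (1 <= lo <= hi):
            raise ConfigError(
                f"genotypes_per_population must satisfy 1 <= lo <= hi, got {lo, hi}"
            )
        if self.controls_per_batch < 0:
            raise ConfigError(
                f"controls_per_batch must be >= 0, got {self.controls_per_batch}"
            )
        if self.ion_mode not in ("positive", "negative"):
            raise ConfigError(f"ion_mode must be positive/negative, got {self.ion_mode!r}")
        if self.total_genotypes is not None:
            if not (lo * self.n_populations <= self.total_genotypes <= hi * self.n_populations):
                raise ConfigError(
                    "total_genotypes out of reach for genotypes_per_population range"
                )


def default_design(seed: int = 0) -> DesignSpec:
    """Fast default preset: 10 populations x 6 genotypes x 5 replicates,
    12 batches with 2 bulk controls each."""
    return DesignSpec(seed=seed)


def full_design(seed: int = 0) -> DesignSpec:
    """Full survey-scale preset: 23 populations, 3-25 genotypes per
    population pinned to 233 genotypes total, 5 clonal replicates, 36
    randomized batches."""
    return DesignSpec(
        n_populations=23,
        genotypes_per_population=(3, 25),
        n_replicates=5,
        n_batches=36,
        controls_per_batch=2,
        seed=seed,
        total_genotypes=233,
    )


def _population_names(n: int) -> list[str]:
    # The first two populations carry the distinct presence/absence
    # signature (North-African-ecotype analogue); named for readability.
    names = ["PG238", "Tunisia"]
    names += [f"pop{i:02d}" for i in range(3, n + 1)]
    return names[:n]


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Sample metadata: one row per sample (genotype x replicate, plus
    per-batch bulk controls), batches randomized over all samples."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    lo, hi = spec.genotypes_per_population
    counts = rng.integers(lo, hi + 1, size=spec.n_populations)
    if spec.total_genotypes is not None:
        # nudge random entries within bounds until the total matches
        while counts.sum() != spec.total_genotypes:
            i = rng.integers(spec.n_populations)
            step = int(np.sign(spec.total_genotypes - counts.sum()))
            if lo <= counts[i] + step <= hi:
                counts[i] += step
    pops = _population_names(spec.n_populations)

    rows = []
    g = 0
    for pop, cnt in zip(pops, counts):
        for _ in range(cnt):
            g += 1
            for rep in range(1, spec.n_replicates + 1):
                rows.append((pop, f"g{g:03d}", rep))
    # randomized batch layout: shuffle all slots, deal round-robin
    order = rng.permutation(len(rows))
    batches = [f"b{(i % spec.n_batches) + 1:02d}" for i in range(len(rows))]
    batch_of = dict(zip(order.tolist(), batches))

    records = []
    for i, (pop, geno, rep) in enumerate(rows):
        records.append({
            "sample_id": f"s{i + 1:04d}",
            "population": pop,
            "genotype": geno,
            "replicate": rep,
            "batch": batch_of[i],
            "ion_mode": spec.ion_mode,
            "is_control": False,
        })
    for b in range(1, spec.n_batches + 1):
        for c in range(1, spec.controls_per_batch + 1):
            records.append({
                "sample_id": f"ctrl_b{b:02d}_{c}",
                "population": "control",
                "genotype": "control",
                "replicate": c,
                "batch": f"b{b:02d}",
                "ion_mode": spec.ion_mode,
                "is_control": True,
            })
    meta = pd.DataFrame.from_records(records)

    # guarantee at least one genotype spans >= 2 batches where possible
    if spec.n_batches >= 2 and spec.n_replicates >= 2:
        spans = meta[~meta.is_control].groupby("genotype")["batch"].nunique()
        if (spans < 2).all():  # pragma: no cover - round-robin makes this rare
            first = meta.index[~meta.is_control][0]
            other = meta.loc[~meta.is_control & (meta.batch != meta.loc[first, "batch"])].index[0]
            meta.loc[first, "batch"], meta.loc[other, "batch"] = (
                meta.loc[other, "batch"], meta.loc[first, "batch"])
    return meta


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class TrueMetabolite:
    name: str
    aglycone: str | None           # key into the aglycone library
    moieties: list[str]            # moiety names, aglycone-outward
    neutral_formula: chem.Formula
    adduct: str
    true_mz: float
    true_rt: float
    carbon_count: int
    population_presence: dict[str, float]
    n_isomer_splits: int = 1
    isomer_spacing: float = 0.2    # minutes between consecutive isomers
    base_intensity: float = 1e6
    kind: str = "invariant"        # invariant | quantitative | exclusive | absent

    @property
    def is_differential(self) -> bool:
        vals = list(self.population_presence.values())
        return max(vals) != min(vals)

    def rendered_name(self) -> str:
        ag = AGLYCONE_LIBRARY[self.aglycone].symbol if self.aglycone else "?"
        syms = [MOIETY_LIBRARY[m].symbol for m in self.moieties]
        return "-".join([ag] + syms)


@dataclass
class BatchEffectSpec:
    """Per-batch systematic effects. ``location_shift`` (per-batch,
    per-peak, on log intensity) is realized at render time once the peak
    rows exist, from ``location_sd``."""

    rt_drift: np.ndarray            # minutes, one per batch
    scale_factor: np.ndarray        # multiplies log-scale noise sd, one per batch
    location_sd: float = 0.5
    max_drift: float = 0.25
    location_shift: np.ndarray | None = None  # (n_peaks, n_batches), filled by render

    def validate(self) -> None:
        if np.any(self.scale_factor <= 0):
            raise ConfigError("scale_factor must be > 0")
        if np.any(np.abs(self.rt_drift) > self.max_drift + 1e-12):
            raise ConfigError("rt_drift exceeds configured maximum")


@dataclass
class TruthSet:
    metabolites: list[TrueMetabolite]
    batch_effects: BatchEffectSpec
    injected_outliers: list[tuple[str, str]] = field(default_factory=list)
    isotope_partners: dict[str, list[str]] = field(default_factory=dict)
    #: provenance: peak row id -> list of (metabolite name, isomer index, isotope level)
    row_members: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def differential_names(self) -> list[str]:
        return [m.name for m in self.metabolites if m.is_differential]

    @property
    def metabolites_by_name(self) -> dict[str, TrueMetabolite]:
        return {m.name: m for m in self.metabolites}


@dataclass(frozen=True)
class MetaboliteConfig:
    """What the simulated metabolome contains.

    Defaults emulate the flavonoid-glycoside / alkaloid chemistry of a
    temperate grass: a handful of named compounds with known
    population-specific behavior plus randomly composed glycosides.
    """

    n_metabolites: int = 200
    n_quantitative: int = 12       # lognormal population multipliers (includes The-Rha)
    quantitative_sd: float = 1.0   # exact log-sd of population multipliers
    genotype_sd: float = 0.7       # biological log-sd between genotypes
    base_log10_range: tuple[float, float] = (5.2, 6.5)
    # quantitative metabolites stay moderate so the presence/absence
    # signature, not quantitative scatter, dominates population profiles
    quantitative_base_log10_range: tuple[float, float] = (5.3, 6.0)
    rt_range: tuple[float, float] = (2.0, 9.0)
    max_carbons: int = 40          # keeps [M]/[M+1] > 2 attainable
    include_named_compounds: bool = True
    all_invariant: bool = False    # null metabolome for calibration runs
    isotope_levels: int = 3        # [M], [M+1], [M+2]

    def validate(self) -> None:
        if self.n_metabolites < 1:
            raise ConfigError("n_metabolites must be >= 1")
        if not self.all_invariant and self.n_quantitative > self.n_metabolites:
            raise ConfigError("n_quantitative exceeds n_metabolites")


def _formula_for(aglycone: str, moieties: list[str]) -> chem.Formula:
    f = AGLYCONE_LIBRARY[aglycone].formula
    if f is None:
        raise ConfigError(f"aglycone {aglycone} has no formula")
    for m in moieties:
        f = f + MOIETY_LIBRARY[m].formula
    return f


def _make_metabolite(
    name: str,
    aglycone: str,
    moieties: list[str],
    rt: float,
    base: float,
    presence: dict[str, float],
    adduct: str,
    kind: str,
    n_isomer_splits: int = 1,
) -> TrueMetabolite:
    formula = _formula_for(aglycone, moieties)
    return TrueMetabolite(
        name=name,
        aglycone=aglycone,
        moieties=list(moieties),
        neutral_formula=formula,
        adduct=adduct,
        true_mz=adduct_mz(monoisotopic_mass(formula), adduct),
        true_rt=rt,
        carbon_count=formula["C"],
        population_presence=presence,
        base_intensity=base,
        kind=kind,
        n_isomer_splits=n_isomer_splits,
    )


def simulate_truth(spec: DesignSpec, config: MetaboliteConfig | None = None) -> TruthSet:
    """Build the ground-truth metabolome plus batch-effect parameters.

    Guarantees (for the default config with >= 3 populations): at least one
    metabolite absent in a designated population pair, at least one present
    in only one population, one isomer pair at close RT (thesinine
    rhamnoside analogue), and isotope envelopes with [M+1]/[M] following the
    binomial 13C model.
    """
    spec.validate()
    config = config or MetaboliteConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    pops = _population_names(spec.n_populations)
    adduct = "[M+H]+" if spec.ion_mode == "positive" else "[M-H]-"

    def all_pops(v: float = 1.0) -> dict[str, float]:
        return {p: v for p in pops}

    def quantitative_presence() -> dict[str, float]:
        # standardized to an exact log-sd so every draw is genuinely
        # differential at the configured effect size
        z = rng.normal(size=len(pops))
        z = (z - z.mean()) / z.std() * config.quantitative_sd
        return {p: float(np.exp(zi)) for p, zi in zip(pops, z)}

    mets: list[TrueMetabolite] = []

    if config.include_named_compounds and not config.all_invariant and len(pops) >= 3:
        pair = set(pops[:2])           # PG238 + Tunisia analogues
        absent_pair = {p: (0.0 if p in pair else 1.0) for p in pops}
        only_first = {p: (1.0 if p == pops[0] else 0.0) for p in pops}
        only_second = {p: (1.0 if p == pops[1] else 0.0) for p in pops}

        # K-derived glycosides absent in the two distinct populations:
        # strong peaks so the shared signature dominates population profiles.
        mets.append(_make_metabolite(
            "K-Glc-maGlc", "kaempferol", ["hexose", "malonylhexose"],
            4.15, 1e7, dict(absent_pair), adduct, "absent"))
        mets.append(_make_metabolite(
            "K-Glc", "kaempferol", ["hexose"],
            4.04, 1e7, dict(absent_pair), adduct, "absent"))
        mets.append(_make_metabolite(
            "K-Glc-feruloylGlc", "kaempferol", ["hexose", "feruloylhexose"],
            6.10, 1e7, dict(absent_pair), adduct, "absent"))
        mets.append(_make_metabolite(
            "K", "kaempferol", [],
            4.70, 1e7, dict(absent_pair), adduct, "absent"))
        # Q/I-derived glycosides exclusive to the first population
        mets.append(_make_metabolite(
            "I-acGlc-Rha", "isorhamnetin", ["acetylhexose", "deoxyhexose"],
            5.46, 3.2e6, dict(only_first), adduct, "exclusive"))
        mets.append(_make_metabolite(
            "Q-acGlc", "quercetin", ["acetylhexose"],
            5.59, 3.2e6, dict(only_first), adduct, "exclusive"))
        mets.append(_make_metabolite(
            "I-acGlc", "isorhamnetin", ["acetylhexose"],
            5.89, 3.2e6, dict(only_first), adduct, "exclusive"))
        # thesinine exclusive to the second population
        mets.append(_make_metabolite(
            "The", "thesinine", [],
            5.17, 3.2e6, dict(only_second), adduct, "exclusive"))
        # thesinine rhamnoside: quantitative, two isomers 0.2 min apart
        mets.append(_make_metabolite(
            "The-Rha", "thesinine", ["deoxyhexose"],
            4.58, 10 ** 6.0, quantitative_presence(), adduct, "quantitative",
            n_isomer_splits=2))
        # chlorogenic acid: invariant, three closely eluting isomers
        mets.append(_make_metabolite(
            "CGA", "chlorogenic acid", [],
            3.84, 1e6, all_pops(), adduct, "invariant",
            n_isomer_splits=3))
        mets[-1].isomer_spacing = 0.18

    # remaining quantitative metabolites
    n_quant_left = 0 if config.all_invariant else max(
        0, config.n_quantitative - sum(m.kind == "quantitative" for m in mets))

    aglycone_pool = ["kaempferol", "quercetin", "isorhamnetin", "thesinine",
                     "chlorogenic acid"]
    moiety_pool = list(MOIETY_LIBRARY)

    def random_combo() -> tuple[str, list[str]]:
        ag = aglycone_pool[rng.integers(len(aglycone_pool))]
        k = int(rng.integers(0, 4))
        ms = sorted(moiety_pool[i] for i in rng.integers(0, len(moiety_pool), size=k))
        return ag, ms

    # keep random metabolites mass-isolated from every named/differential
    # compound so truth-recovery and aggregation checks are unconfounded
    differential_mzs = [m.true_mz for m in mets]

    def isolated(mz: float) -> bool:
        return all(abs(mz - d) / d * 1e6 > 60 for d in differential_mzs)

    idx = 0
    while len(mets) < config.n_metabolites:
        ag, ms = random_combo()
        formula = _formula_for(ag, ms)
        if formula["C"] > config.max_carbons:
            continue
        mz = adduct_mz(monoisotopic_mass(formula), adduct)
        rt = float(rng.uniform(*config.rt_range))
        base = float(10 ** rng.uniform(*config.base_log10_range))
        if n_quant_left > 0 and isolated(mz):
            presence = quantitative_presence()
            base = float(10 ** rng.uniform(*config.quantitative_base_log10_range))
            kind = "quantitative"
            n_quant_left -= 1
            differential_mzs.append(mz)
        else:
            if not isolated(mz) and n_quant_left > 0:
                # keep drawing; this combo would shadow a differential m/z
                continue
            if not isolated(mz):
                continue
            presence = all_pops()
            kind = "invariant"
        idx += 1
        mets.append(TrueMetabolite(
            name=f"met{idx:03d}",
            aglycone=ag,
            moieties=ms,
            neutral_formula=formula,
            adduct=adduct,
            true_mz=mz,
            true_rt=rt,
            carbon_count=formula["C"],
            population_presence=presence,
            base_intensity=base,
            kind=kind,
        ))

    drift = rng.uniform(-0.25, 0.25, size=spec.n_batches)
    scale = np.exp(rng.normal(0.0, 0.15, size=spec.n_batches))
    batch_effects = BatchEffectSpec(rt_drift=drift, scale_factor=scale)
    batch_effects.validate()

    # consistency check: true_mz vs formula + adduct
    for m in mets:
        expect = adduct_mz(monoisotopic_mass(m.neutral_formula), m.adduct)
        assert abs(expect - m.true_mz) < 1e-4, m.name

    return TruthSet(metabolites=mets, batch_effects=batch_effects)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _isotope_fractions(n_carbons: int, levels: int) -> list[float]:
    """Intensity of [M+k] relative to [M] under the binomial 13C model."""
    r = P_13C / (1.0 - P_13C)
    return [math.comb(n_carbons, k) * r ** k for k in range(levels)]


def _cluster_by_gap(values: np.ndarray, gap: float) -> list[np.ndarray]:
    """1-D single-linkage clustering: split sorted values at gaps > ``gap``.
    Returns index arrays into ``values``."""
    order = np.argsort(values, kind="stable")
    sv = values[order]
    breaks = np.where(np.diff(sv) > gap)[0]
    return [order[idx] for idx in np.split(np.arange(len(sv)), breaks + 1)]


def render_intensity_matrix(
    truth: TruthSet,
    design: pd.DataFrame,
    noise_cv: float = 0.2,
    seed: int = 0,
    *,
    genotype_sd: float = 0.7,
    batch_location_sd: float | None = None,
    apply_rt_drift: bool = True,
    baseline_floor: float = 1e3,
    rt_gap_tol: float = 0.05,
    residual_drift_factor: float = 0.1,
    sample_rt_jitter: float = 0.03,
    independent_noise_frac: float = 0.25,
    mass_error_ppm: float = 5.0,
    n_outliers: int = 40,
    outlier_factor: float = 10.0,
    m2_min_intensity_factor: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render detected peak rows and per-sample intensities.

    Peak rows emerge from an alignment-like step: for every group of ions
    sharing an m/z channel, per-batch apex RTs (isomer RT + batch drift) are
    clustered by gap; each RT cluster becomes one detected row. A sample
    whose batch does not contribute to a row is filled at the baseline noise
    floor, which is how closely eluting isomers end up split across more
    rows than there are isomers.

    Alignment resolves batch drift for well-separated peaks but cannot for
    closely eluting isomers, so the full per-batch drift is applied only to
    metabolites with ``n_isomer_splits > 1``; single-isomer metabolites see
    the residual drift left after alignment (``residual_drift_factor`` of
    the batch drift, small enough not to split rows).

    Technical noise is multiplicative log-normal with replicate cv ~=
    ``noise_cv``. Most of it is shared across the isotope envelope of a
    compound within a sample (injection/extraction variability scales the
    whole spectrum); only a small residual (``independent_noise_frac`` of
    ``noise_cv``) is independent per detected row. Batch location shifts
    (log scale, sd ``batch_location_sd``, default from the truth's
    BatchEffectSpec) and per-batch noise-scale factors apply on the log
    scale.

    Mutates ``truth``: fills ``isotope_partners``, ``injected_outliers``,
    ``row_members`` and ``batch_effects.location_shift``.
    """
    if not (0 <= noise_cv < 1):
        raise ConfigError(f"noise_cv must be in [0, 1), got {noise_cv}")
    required = {"sample_id", "population", "genotype", "replicate", "batch", "is_control"}
    if not required.issubset(design.columns):
        raise ConfigError(f"design missing columns {required - set(design.columns)}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    be = truth.batch_effects
    batches = sorted(design["batch"].unique())
    if len(batches) != len(be.rt_drift):
        raise ConfigError(
            f"design has {len(batches)} batches but batch effects specify "
            f"{len(be.rt_drift)}")
    b_index = {b: i for i, b in enumerate(batches)}
    loc_sd = be.location_sd if batch_location_sd is None else batch_location_sd
    drift = be.rt_drift if apply_rt_drift else np.zeros_like(be.rt_drift)

    ion_mode = design["ion_mode"].iloc[0]
    pops = design["population"].unique()

    # --- ion instances: (metabolite, isomer, isotope level) ---------------
    instances = []  # (met_idx, isomer, level, ion_mz, frac)
    for mi, met in enumerate(truth.metabolites):
        fracs = _isotope_fractions(met.carbon_count, 3)
        for k in range(met.n_isomer_splits):
            for level, frac in enumerate(fracs):
                if level == 2 and met.base_intensity * frac < \
                        m2_min_intensity_factor * baseline_floor:
                    continue
                instances.append(
                    (mi, k, level, met.true_mz + level * C13_C12_SPACING, frac))

    # --- m/z channels: group instances within 20 ppm ----------------------
    inst_mz = np.array([t[3] for t in instances])
    order = np.argsort(inst_mz)
    channels: list[list[int]] = []
    for j in order:
        if channels and (inst_mz[j] - inst_mz[channels[-1][-1]]) / inst_mz[j] * 1e6 <= 20:
            channels[-1].append(j)
        else:
            channels.append([j])

    # --- rows: RT-cluster per-batch apexes within each channel ------------
    rows = []  # dict per row
    for chan in channels:
        pts_inst, pts_batch, pts_rt = [], [], []
        for j in chan:
            mi, k, level, _, _ = instances[j]
            met = truth.metabolites[mi]
            isomer_rt = met.true_rt + k * met.isomer_spacing
            factor = 1.0 if met.n_isomer_splits > 1 else residual_drift_factor
            for b in batches:
                pts_inst.append(j)
                pts_batch.append(b)
                pts_rt.append(isomer_rt + factor * drift[b_index[b]])
        pts_rt_arr = np.array(pts_rt)
        for cluster in _cluster_by_gap(pts_rt_arr, rt_gap_tol):
            members = {}
            for ci in cluster:
                members.setdefault(pts_batch[ci], []).append(pts_inst[ci])
            apexes = pts_rt_arr[cluster]
            true_ion_mz = float(np.mean([instances[pts_inst[ci]][3] for ci in cluster]))
            err = rng.uniform(-mass_error_ppm, mass_error_ppm)
            det_mz = true_ion_mz * (1 + err * 1e-6)
            rows.append({
                "members": members,           # batch -> [instance index]
                "rt": float(np.mean(apexes)),
                "rtmin": float(np.min(apexes)) - 0.05,
                "rtmax": float(np.max(apexes)) + 0.05,
                "mz": det_mz,
                "mzmin": det_mz * (1 - 10e-6),
                "mzmax": det_mz * (1 + 10e-6),
            })

    # deterministic row order by m/z then rt; unique peak ids
    rows.sort(key=lambda r: (r["mz"], r["rt"]))
    seen = {}
    for r in rows:
        pid = format_peak_id(ion_mode, r["mz"], r["rt"])
        while pid in seen:
            r["mz"] = r["mz"] * (1 + 1e-6)  # nudge by 1 ppm on collision
            pid = format_peak_id(ion_mode, r["mz"], r["rt"])
        seen[pid] = True
        r["peak_id"] = pid

    n_rows, n_samp = len(rows), len(design)

    # genotype biological factors and control composition, per metabolite
    genos = design["genotype"].unique()
    g_index = {g: i for i, g in enumerate(genos)}
    n_mets = len(truth.metabolites)
    geno_fac = np.exp(rng.normal(0.0, genotype_sd, size=(n_mets, len(genos)))) \
        if genotype_sd > 0 else np.ones((n_mets, len(genos)))
    control_mult = np.array([
        float(np.mean([v for v in m.population_presence.values()]))
        for m in truth.metabolites
    ])

    sample_batch = design["batch"].map(b_index).to_numpy()
    sample_geno = design["genotype"].map(g_index).to_numpy()
    sample_pop = design["population"].to_numpy()
    is_control = design["is_control"].to_numpy()

    # --- assign each (instance, sample) contribution to one row -----------
    # single-isomer metabolites: deterministic by the sample's batch.
    # isomer-split metabolites: the sample's own apex (isomer RT + batch
    # drift + per-sample jitter) picks the nearest row — peak assignment
    # varies sample to sample, as misaligned real data does, so batch
    # correction cannot absorb the fill pattern.
    inst_batch_row: dict[tuple[int, str], int] = {}
    for ri, r in enumerate(rows):
        for b, lst in r["members"].items():
            for j in lst:
                inst_batch_row[(j, b)] = ri
    row_centers = np.array([r["rt"] for r in rows])
    presence_cache: dict[int, np.ndarray] = {}
    jitter_cache: dict[tuple[int, int], np.ndarray] = {}

    # shared technical noise: one draw per compound isomer and sample,
    # scaling every isotope level together
    sigma_shared = math.sqrt(
        math.log(1.0 + (noise_cv * math.sqrt(1 - independent_noise_frac ** 2)) ** 2)
    ) if noise_cv > 0 else 0.0
    sigma_indep = math.sqrt(
        math.log(1.0 + (noise_cv * independent_noise_frac) ** 2)
    ) if noise_cv > 0 else 0.0
    shared_noise_cache: dict[tuple[int, int], np.ndarray] = {}
    # batch location shifts act on the compound, hence identically on every
    # isotope level of an isomer — drawn per (metabolite, isomer, batch)
    loc_cache: dict[tuple[int, int], np.ndarray] = {}

    base_arr = np.zeros((n_rows, n_samp))
    for j, (mi, k, level, ion_mz, frac) in enumerate(instances):
        met = truth.metabolites[mi]
        if mi not in presence_cache:
            presence_cache[mi] = np.array(
                [met.population_presence.get(p, 0.0) for p in sample_pop])
        mult = np.where(is_control, control_mult[mi], presence_cache[mi])
        if (mi, k) not in shared_noise_cache:
            shared_noise_cache[(mi, k)] = rng.normal(size=n_samp)
            loc_cache[(mi, k)] = (rng.normal(0.0, loc_sd, size=len(batches))
                                  if loc_sd > 0 else np.zeros(len(batches)))
        shared = np.exp(sigma_shared * be.scale_factor[sample_batch] *
                        shared_noise_cache[(mi, k)] +
                        loc_cache[(mi, k)][sample_batch])
        contrib = (met.base_intensity * frac * mult * shared *
                   geno_fac[mi, sample_geno] / met.n_isomer_splits)
        if met.n_isomer_splits > 1:
            key = (mi, k)
            if key not in jitter_cache:
                jitter_cache[key] = rng.normal(0.0, sample_rt_jitter, size=n_samp)
            isomer_rt = met.true_rt + k * met.isomer_spacing
            apex = isomer_rt + drift[sample_batch] + jitter_cache[key]
            cand = sorted({inst_batch_row[(j, b)] for b in batches
                           if (j, b) in inst_batch_row})
            choice = np.array(cand)[
                np.argmin(np.abs(apex[:, None] - row_centers[cand][None, :]),
                          axis=1)]
        else:
            choice = np.array([inst_batch_row[(j, batches[bi])]
                               for bi in sample_batch])
        np.add.at(base_arr, (choice, np.arange(n_samp)), contrib)

    # record the realized per-peak, per-batch shifts (each pure row carries
    # its compound's shift vector)
    def _row_compound(r):
        lst = next(iter(r["members"].values()))
        mi, k, _, _, _ = instances[lst[0]]
        return (mi, k)

    be.location_shift = np.vstack([
        loc_cache.get(_row_compound(r), np.zeros(len(batches))) for r in rows
    ]) if rows else np.zeros((0, len(batches)))

    values = np.empty((n_rows, n_samp))
    for ri in range(n_rows):
        base = base_arr[ri]
        present = base > 0
        z = rng.normal(size=n_samp)
        noise = sigma_indep * be.scale_factor[sample_batch] * z
        vals = np.where(
            present,
            np.exp(np.log(np.where(present, base, 1.0)) + noise),
            baseline_floor * rng.uniform(0.5, 1.5, size=n_samp),
        )
        values[ri] = vals

    matrix = pd.DataFrame(values, index=[r["peak_id"] for r in rows],
                          columns=design["sample_id"].to_list())
    matrix.index.name = "peak_id"

    # --- provenance + isotope partner links -------------------------------
    truth.row_members = {
        r["peak_id"]: sorted({
            (truth.metabolites[instances[j][0]].name, instances[j][1], instances[j][2])
            for lst in r["members"].values() for j in lst
        })
        for r in rows
    }
    # match [M]/[M+1]/[M+2] rows by (metabolite/isomer set, batch partition):
    # isotope levels co-elute, so partner rows share both exactly
    partner_map: dict[str, list[str]] = {}
    by_sig: dict[tuple, dict[int, str]] = {}
    for r in rows:
        sig_members = tuple(sorted({
            (instances[j][0], instances[j][1])
            for lst in r["members"].values() for j in lst}))
        sig_batches = tuple(sorted(r["members"]))
        levels = {instances[j][2] for lst in r["members"].values() for j in lst}
        if len(levels) != 1:
            continue
        by_sig.setdefault((sig_members, sig_batches), {})[levels.pop()] = r["peak_id"]
    for sig, lev in by_sig.items():
        if 0 in lev:
            partners = [lev[k] for k in (1, 2) if k in lev]
            if partners:
                partner_map[lev[0]] = partners
    truth.isotope_partners = partner_map

    # --- outlier injection -------------------------------------------------
    annot_links = {r["peak_id"]: partner_map.get(r["peak_id"], []) for r in rows}
    outliers: list[tuple[str, str]] = []
    if n_outliers > 0 and outlier_factor != 1.0:
        mono_rows = [ri for ri, r in enumerate(rows)
                     if r["peak_id"] in partner_map
                     and len(r["members"]) == len(batches)]
        exp_samples = np.flatnonzero(~is_control)
        used = set()
        tries = 0
        while len(outliers) < n_outliers and tries < n_outliers * 50 and mono_rows:
            tries += 1
            ri = mono_rows[rng.integers(len(mono_rows))]
            si = int(exp_samples[rng.integers(len(exp_samples))])
            geno = design["genotype"].iloc[si]
            if (ri, geno) in used:
                continue
            if values[ri, si] <= 2 * baseline_floor:
                continue
            used.add((ri, geno))
            values[ri, si] *= outlier_factor
            outliers.append((design["sample_id"].iloc[si], rows[ri]["peak_id"]))
        matrix.iloc[:, :] = values
    truth.injected_outliers = outliers

    annot = pd.DataFrame({
        "peak_id": [r["peak_id"] for r in rows],
        "mz": [r["mz"] for r in rows],
        "rt": [r["rt"] for r in rows],
        "rtmin": [r["rtmin"] for r in rows],
        "rtmax": [r["rtmax"] for r in rows],
        "mzmin": [r["mzmin"] for r in rows],
        "mzmax": [r["mzmax"] for r in rows],
        "adduct": "unknown",
        "isotope_links": [";".join(annot_links[r["peak_id"]]) for r in rows],
    })
    return matrix, annot


# ---------------------------------------------------------------------------
# Pseudo-spectra
# ---------------------------------------------------------------------------

def render_pseudo_spectra(
    truth: TruthSet,
    relative_intensities: tuple[float, ...] = (100.0, 80.0, 60.0, 40.0),
) -> list[Spectrum]:
    """In-source-fragmentation pseudo-spectra for glycoside metabolites.

    Each record holds the (de)protonated parent plus fragment ions at the
    parent minus successive neutral losses, outermost moiety first, ending
    at the aglycone ion.
    """
    spectra = []
    for met in truth.metabolites:
        ions = [(met.true_mz, relative_intensities[0])]
        mz = met.true_mz
        for i, moiety in enumerate(reversed(met.moieties)):
            mz -= MOIETY_LIBRARY[moiety].loss_mass
            rel = relative_intensities[min(i + 1, len(relative_intensities) - 1)]
            ions.append((mz, rel))
        spectra.append(Spectrum(
            name=met.rendered_name(),
            precursor_mz=met.true_mz,
            ions=ions,
            metadata={"Comment": f"truth={met.name} kind={met.kind} "
                                 f"formula={met.neutral_formula}"},
        ))
    return spectra
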