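"""Synthetic urine spectrum and cohort generator.

Every downstream stage is exercised against spectra produced here: Lorentzian
multiplets built from J-coupling trees, a TSP reference singlet, per-sample
chemical-shift jitter, a smooth random baseline, a water-suppression dead
zone and additive Gaussian noise. Cohorts are drawn with log-normal
between-individual and within-individual (day-to-day) layers calibrated by
CV%, plus sex/BMI covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures_io import (
    CohortDesign,
    ConcentrationTable,
    MetaboliteSignature,
    ProtonGroup,
    Spectrum,
    packaged_data_path,
)

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "TSP_SIGNATURE",
    "multiplet_pattern",
    "lorentzian",
    "render_sample",
    "simulate_cohort",
    "simulate_replicates",
    "simulate_genotypes",
    "load_cohort_calibration",
]

#: 9 equivalent trimethylsilyl protons at 0 ppm; chemical-shift and
#: concentration reference.
TSP_SIGNATURE = MetaboliteSignature(
    name="tsp",
    groups=(ProtonGroup(center_ppm=0.0, n_protons=9, couplings=(), mobility_ppm=0.002),),
    pathway="reference",
)

#: area units per (umol/L in tube x proton); arbitrary but fixed so that
#: simulated and fitted areas live on one scale.
AREA_PER_UMOL_PROTON = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the spectrum generator; defaults are desk-scale."""

    ppm_max: float = 10.0
    ppm_min: float = -0.5
    n_points: int = 32768
    linewidth_hz: float = 1.0
    noise_sd: float = 5e-4          # fraction of the TSP peak height
    jitter: float = 1.0             # scale on each group's mobility window
    baseline_amplitude: float = 1e-3  # fraction of TSP peak height
    water_zone: tuple = (4.50, 5.00)
    water_attenuation: float = 1e-3
    tsp_conc_mmol_per_L: float = 0.5
    dilution: float = 700.0 / 630.0  # tube volume / urine volume
    frequency_mhz: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ppm_max > self.ppm_min:
            raise ValueError("ppm_max must exceed ppm_min")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")

    def axis(self) -> np.ndarray:
        """Decreasing ppm axis."""
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)

    @property
    def linewidth_ppm(self) -> float:
        return self.linewidth_hz / self.frequency_mhz

    @property
    def tsp_area(self) -> float:
        return (
            self.tsp_conc_mmol_per_L * 1000.0
            * TSP_SIGNATURE.groups[0].n_protons
            * AREA_PER_UMOL_PROTON
        )

    @property
    def tsp_peak_height(self) -> float:
        return 2.0 * self.tsp_area / (math.pi * self.linewidth_ppm)


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort: pre-dilution concentrations,
    design, and the realized per-group shift offsets of each sample."""

    concentrations: ConcentrationTable  # umol/L, original urine
    design: CohortDesign
    shift_offsets: dict = field(default_factory=dict)  # sample_id -> {(met, gi): ppm}


def multiplet_pattern(couplings, frequency_mhz: float):
    """First-order multiplet line positions and weights.

    Iterated convolution of the (m+1)-line binomial pattern of each
    ``(J_hz, m)`` coupling, line spacing ``J_hz / frequency_mhz`` ppm.
    Returns a list of ``(offset_ppm, weight)`` sorted by offset; weights sum
    to 1 and the pattern is symmetric about 0. No couplings -> singlet.
    """
    offsets = np.array([0.0])
    weights = np.array([1.0])
    for j_hz, m in couplings:
        if j_hz < 0:
            raise ValueError("J coupling must be >= 0")
        m = int(m)
        if m < 1:
            raise ValueError("coupling multiplicity must be >= 1")
        spacing = j_hz / frequency_mhz
        k = np.arange(m + 1)
        sub_off = (k - m / 2.0) * spacing
        sub_w = np.array([math.comb(m, int(i)) for i in k], dtype=float) / 2**m
        offsets = (offsets[:, None] + sub_off[None, :]).ravel()
        weights = (weights[:, None] * sub_w[None, :]).ravel()
    # merge coincident lines (e.g. equal Js)
    order = np.argsort(offsets)
    offsets, weights = offsets[order], weights[order]
    merged_off, merged_w = [], []
    for o, w in zip(offsets, weights):
        if merged_off and abs(o - merged_off[-1]) < 1e-12:
            merged_w[-1] += w
        else:
            merged_off.append(o)
            merged_w.append(w)
    return list(zip(merged_off, merged_w))


def lorentzian(ppm_axis: np.ndarray, center_ppm: float, area: float, fwhm_ppm: float) -> np.ndarray:
    """Unit-normalized Lorentzian: ``(2A/(pi f)) / (1 + (2(x-c)/f)^2)``."""
    if fwhm_ppm <= 0:
        raise ValueError("fwhm_ppm must be positive")
    x = np.asarray(ppm_axis, dtype=float)
    u = 2.0 * (x - center_ppm) / fwhm_ppm
    return (2.0 * area / (math.pi * fwhm_ppm)) / (1.0 + u * u)


def _group_lines(group: ProtonGroup, frequency_mhz: float):
    return multiplet_pattern(group.couplings, frequency_mhz)


def _signature_map(signatures) -> dict:
    return {s.name: s for s in signatures}


def render_sample(
    signatures,
    concentrations_in_tube: dict,
    config: SimulationConfig,
    seed: int | None = None,
    sample_id: str = "sample",
    jitter_offsets: dict | None = None,
):
    """Render one spectrum from in-tube concentrations (umol/L).

    Returns ``(Spectrum, shift_offsets)`` where ``shift_offsets`` maps
    ``(metabolite, group_index)`` to the realized jitter in ppm. Pass
    ``jitter_offsets`` to freeze the shifts (replicates from one tube).
    """
    sig_map = _signature_map(signatures)
    unknown = sorted(set(concentrations_in_tube) - set(sig_map))
    if unknown:
        raise KeyError(f"no signature for metabolite(s): {unknown}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    axis = config.axis()
    fwhm = config.linewidth_ppm
    signal = np.zeros_like(axis)

    offsets_out: dict = {}
    render_list = [(TSP_SIGNATURE, config.tsp_conc_mmol_per_L * 1000.0)]
    render_list += [(sig_map[name], conc) for name, conc in concentrations_in_tube.items()]
    for sig, conc in render_list:
        for gi, group in enumerate(sig.groups):
            key = (sig.name, gi)
            if jitter_offsets is not None:
                off = jitter_offsets.get(key, 0.0)
            else:
                half = group.mobility_ppm * config.jitter
                off = rng.uniform(-half, half) if half > 0 else 0.0
            offsets_out[key] = off
            if conc <= 0:
                continue
            group_area = conc * group.n_protons * AREA_PER_UMOL_PROTON
            center = group.center_ppm + off
            for line_off, w in _group_lines(group, config.frequency_mhz):
                signal += lorentzian(axis, center + line_off, group_area * w, fwhm)

    # smooth baseline: 3 broad Gaussians with signed random amplitudes
    if config.baseline_amplitude > 0:
        amp_scale = config.baseline_amplitude * config.tsp_peak_height
        for _ in range(3):
            c = rng.uniform(config.ppm_min, config.ppm_max)
            fwhm_b = rng.uniform(1.0, 3.0)
            a = rng.uniform(-1.0, 1.0) * amp_scale
            sigma = fwhm_b / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            signal += a * np.exp(-0.5 * ((axis - c) / sigma) ** 2)

    lo, hi = config.water_zone
    in_zone = (axis >= lo) & (axis <= hi)
    signal[in_zone] *= config.water_attenuation

    if config.noise_sd > 0:
        signal = signal + rng.normal(
            0.0, config.noise_sd * config.tsp_peak_height, size=axis.shape
        )

    spec = Spectrum(
        sample_id=sample_id,
        ppm=axis,
        intensity=signal,
        frequency_mhz=config.frequency_mhz,
        metadata={"synthetic": "true"},
    )
    return spec, offsets_out


def _sigma_from_cv(cv_percent: float) -> float:
    if cv_percent < 0:
        raise ValueError("CV% must be >= 0")
    c = cv_percent / 100.0
    return math.sqrt(math.log1p(c * c))


def load_cohort_calibration() -> pd.DataFrame:
    """Packaged per-metabolite simulation means and CV% calibration targets."""
    return pd.read_csv(
        packaged_data_path("cohort_calibration.tsv"), sep="\t", comment="#", index_col=0
    )


def _lognormal_factor(rng, sigma: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal factor."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def simulate_cohort(
    signatures,
    n_individuals: int,
    inter_cv: dict,
    intra_cv: dict | None = None,
    days_per_individual: int = 1,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    mean_conc: dict | None = None,
    ratio_mode: bool = True,
    bmi_log_effects: dict | None = None,
    render: bool = True,
):
    """Simulate a cohort of urine samples with calibrated CV layers.

    Concentration layers are log-normal: individual geometric levels with
    ``sigma = sqrt(ln(1+(CV_inter/100)^2))`` and day-to-day factors with the
    intra-individual sigma. With ``ratio_mode=True`` (default) the calibrated
    quantity for non-creatinine metabolites is the creatinine *ratio* —
    creatinine is drawn first and metabolite concentrations are
    ratio x creatinine — so that CV targets apply to the
    creatinine-normalized values every reported CV layer is computed on.
    With ``ratio_mode=False`` every metabolite is drawn independently.

    ``bmi_log_effects`` maps metabolite -> log-scale effect per BMI SD.
    Returns ``(spectra, CohortTruth)``; ``spectra`` is empty if
    ``render=False`` (truth-only simulations for statistics tests).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    intra_cv = intra_cv or {}
    sig_map = _signature_map(signatures)
    names = [n for n in inter_cv if n != "creatinine"]
    unknown = sorted(set(names) - set(sig_map))
    if unknown:
        raise KeyError(f"no signature for metabolite(s): {unknown}")
    if "creatinine" not in inter_cv:
        raise ValueError("inter_cv must include creatinine (the normalizer)")
    calib = load_cohort_calibration()
    mean_conc = dict(mean_conc or {})
    for name in ["creatinine"] + names:
        if name not in mean_conc:
            if name not in calib.index:
                raise ValueError(f"no mean concentration for {name!r}")
            mean_conc[name] = float(calib.loc[name, "mean_umol_per_L"])

    # covariates
    individuals = [f"ind{i:04d}" for i in range(n_individuals)]
    sex = rng.integers(0, 2, size=n_individuals)
    bmi = rng.normal(26.0, 4.0, size=n_individuals)
    bmi_z = (bmi - bmi.mean()) / bmi.std(ddof=1) if n_individuals > 1 else np.zeros(n_individuals)
    covariates = pd.DataFrame({"sex": sex, "bmi": bmi}, index=individuals)
    bmi_log_effects = bmi_log_effects or {}

    n_days = max(1, int(days_per_individual))
    order = ["creatinine"] + names

    # individual geometric levels, then day-level factors
    levels = {}
    for name in order:
        sigma = _sigma_from_cv(inter_cv[name])
        levels[name] = mean_conc[name] * _lognormal_factor(rng, sigma, n_individuals)
        beta = bmi_log_effects.get(name, 0.0)
        if beta:
            levels[name] = levels[name] * np.exp(beta * bmi_z)

    rows, sample_ids, sample_ind, sample_day = [], [], [], []
    truth = {name: [] for name in order}
    for i, ind in enumerate(individuals):
        day_factors = {
            name: _lognormal_factor(rng, _sigma_from_cv(intra_cv.get(name, 0.0)), n_days)
            for name in order
        }
        for d in range(n_days):
            sid = f"{ind}_d{d:02d}"
            sample_ids.append(sid)
            sample_ind.append(ind)
            sample_day.append(d)
            creat = levels["creatinine"][i] * day_factors["creatinine"][d]
            truth["creatinine"].append(creat)
            for name in names:
                val = levels[name][i] * day_factors[name][d]
                if ratio_mode:
                    # calibrated value is the ratio to mean creatinine
                    val = val * creat / mean_conc["creatinine"]
                truth[name].append(val)

    conc = pd.DataFrame(truth, index=sample_ids)[order]
    table = ConcentrationTable(conc, units="umol_per_L")
    design = CohortDesign(
        samples=pd.DataFrame(
            {"individual": sample_ind, "replicate_group": pd.NA, "collection_day": sample_day},
            index=sample_ids,
        ),
        covariates=covariates,
    )

    spectra = []
    shift_offsets = {}
    if render:
        for sid in sample_ids:
            in_tube = {name: conc.loc[sid, name] / config.dilution for name in order}
            spec, offs = render_sample(
                signatures,
                in_tube,
                config,
                seed=int(rng.integers(0, 2**63 - 1)),
                sample_id=sid,
            )
            spectra.append(spec)
            shift_offsets[sid] = offs
    return spectra, CohortTruth(table, design, shift_offsets)


def simulate_replicates(
    signatures,
    base_concentrations: dict,
    n_reps: int = 10,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    freeze_jitter: bool = True,
):
    """Render ``n_reps`` replicate spectra of one sample (umol/L in urine).

    Replicates share the truth; noise and baseline are independent.
    ``freeze_jitter`` keeps the chemical-shift offsets identical across
    replicates (they come from one tube).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    in_tube = {k: v / config.dilution for k, v in base_concentrations.items()}
    frozen = None
    if freeze_jitter:
        jitter_rng = np.random.default_rng(int(rng.integers(0, 2**63 - 1)))
        frozen = {}
        for sig in [TSP_SIGNATURE] + [s for s in signatures if s.name in in_tube]:
            for gi, group in enumerate(sig.groups):
                half = group.mobility_ppm * config.jitter
                frozen[(sig.name, gi)] = jitter_rng.uniform(-half, half) if half > 0 else 0.0
    spectra = []
    for r in range(n_reps):
        spec, _ = render_sample(
            signatures,
            in_tube,
            config,
            seed=int(rng.integers(0, 2**63 - 1)),
            sample_id=f"rep{r:02d}",
            jitter_offsets=frozen,
        )
        spectra.append(spec)
    return spectra


def simulate_genotypes(
    n_individuals: int,
    n_variants: int,
    seed: int = 0,
    maf_range: tuple = (0.01, 0.5),
    info_range: tuple = (0.5, 1.0),
    individuals=None,
):
    """Hardy-Weinberg dosage matrix with random MAF and info scores.

    Returns ``(dosages DataFrame individuals x variants, variant_info
    DataFrame with maf/info/chrom/pos)``. Meant as a stand-in for imputed
    genotype data in the association-scan stage.
    """
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=n_variants)
    info = rng.uniform(*info_range, size=n_variants)
    dosages = rng.binomial(2, mafs[None, :], size=(n_individuals, n_variants)).astype(float)
    if individuals is None:
        individuals = [f"ind{i:04d}" for i in range(n_individuals)]
    variant_ids = [f"rs{i:06d}" for i in range(n_variants)]
    dos = pd.DataFrame(dosages, index=individuals, columns=variant_ids)
    vinfo = pd.DataFrame(
        {
            "chrom": rng.integers(1, 23, size=n_variants),
            "pos": np.sort(rng.integers(1, 2**27, size=n_variants)),
            "maf": np.minimum(mafs, 1 - mafs),
            "info": info,
        },
        index=variant_ids,
    )
    return dos, vinfo
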