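"""Constrained total line-shape fitting.

A spectral window is decomposed into Lorentzian components whose internal
structure is fixed by molecular prior knowledge: multiplet line positions and
intensity ratios follow from J-couplings and proton counts, so each
metabolite contributes one free area, one free centre per proton group
(bounded by its mobility window), and one shared linewidth. Remaining free
parameters are a low-order window baseline and optional unconstrained
singlets for unidentified signals. Areas are converted to absolute
concentrations against the TSP reference singlet.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import least_squares, lsq_linear

from .signatures_io import Spectrum, packaged_data_path
from .synthspec import TSP_SIGNATURE, lorentzian, multiplet_pattern

__all__ = [
    "CtlsOptions",
    "FitModel",
    "FitResult",
    "QCError",
    "build_fit_model",
    "fit",
    "detect_unidentified",
    "area_to_concentration",
    "quantify_sample",
    "load_window_plan",
]


class QCError(RuntimeError):
    """Quality-control failure that invalidates quantification (e.g. the
    TSP reference signal is missing)."""


@dataclass(frozen=True)
class CtlsOptions:
    """Fit configuration shared across windows."""

    default_fwhm_hz: float = 1.0
    fwhm_bounds_hz: tuple = (0.3, 5.0)
    baseline_order: int = 1
    width_per_group: bool = False      # default: one linewidth per metabolite
    fix_widths: bool = False
    fix_centers: bool = False
    max_iter: int = 200
    tol: float = 1e-10
    #: metabolites whose stage-one area is below this multiple of the
    #: noise-equivalent area get their centre/width frozen (area stays free);
    #: stops shape parameters wandering across signal-free windows. 0 disables.
    freeze_low_signal_factor: float = 5.0
    water_zone: tuple = (4.50, 5.00)
    detect_threshold: float = 5.0      # x robust noise SD
    max_extra: int = 5
    extra_center_slack_ppm: float = 0.005
    tsp_conc_mmol_per_L: float = 0.5
    dilution: float = 700.0 / 630.0
    suppression_flag_zone: tuple = (4.30, 6.20)


@dataclass
class _MetEntry:
    name: str
    group_centers: np.ndarray       # reference centre per in-window group
    group_mobility: np.ndarray
    effective_protons: int


@dataclass
class FitModel:
    """Constrained component set for one window."""

    window: tuple                    # (high_ppm, low_ppm)
    frequency_mhz: float
    metabolites: list                # list[_MetEntry]
    comp_met: np.ndarray             # component -> metabolite index
    comp_group: np.ndarray           # component -> global group index
    comp_offset: np.ndarray          # multiplet line offset from group centre
    comp_weight: np.ndarray          # relative weight; sums to 1 per metabolite
    n_groups: int
    options: CtlsOptions
    extra_singlets: list = field(default_factory=list)  # (center0, area0) seeds

    @property
    def n_mets(self) -> int:
        return len(self.metabolites)


@dataclass
class FitResult:
    """Fitted parameters and diagnostics for one window."""

    window: tuple
    areas: dict                      # metabolite -> absolute in-window area
    centers: dict                    # metabolite -> fitted group centres (ppm)
    widths: dict                     # metabolite -> fitted FWHM (ppm)
    effective_protons: dict          # metabolite -> protons represented in-window
    baseline_coeffs: np.ndarray
    extra_singlets: list             # (center, area, fwhm) triples
    residual_rms: float
    noise_sd: float
    converged: bool
    n_evaluations: int
    message: str = ""


def build_fit_model(signatures, window, frequency_mhz: float,
                    options: CtlsOptions | None = None) -> FitModel:
    """Enumerate constrained components for every signature whose multiplet
    lines fall fully inside ``window`` (after allowing +/- mobility).

    Signatures with no in-window group are excluded with a warning; an empty
    model raises ``ValueError``.
    """
    options = options or CtlsOptions()
    high, low = window
    if not high > low:
        raise ValueError(f"empty window {window}")
    mets: list[_MetEntry] = []
    comp_met, comp_group, comp_offset, comp_weight = [], [], [], []
    group_counter = 0
    for sig in signatures:
        g_centers, g_mob, g_lines = [], [], []
        for group in sig.groups:
            lines = multiplet_pattern(group.couplings, frequency_mhz)
            span = max(abs(o) for o, _ in lines)
            if (group.center_ppm - group.mobility_ppm - span >= low
                    and group.center_ppm + group.mobility_ppm + span <= high):
                g_centers.append(group.center_ppm)
                g_mob.append(group.mobility_ppm)
                g_lines.append((group.n_protons, lines))
        if not g_centers:
            warnings.warn(f"{sig.name}: no proton group inside window {window}; excluded")
            continue
        eff_protons = sum(n for n, _ in g_lines)
        mi = len(mets)
        mets.append(
            _MetEntry(sig.name, np.array(g_centers), np.array(g_mob), eff_protons)
        )
        for (n_protons, lines), _c in zip(g_lines, g_centers):
            for off, w in lines:
                comp_met.append(mi)
                comp_group.append(group_counter)
                comp_offset.append(off)
                comp_weight.append(n_protons * w / eff_protons)
            group_counter += 1
    if not mets:
        raise ValueError(f"no signature has lines inside window {window}")
    return FitModel(
        window=(high, low),
        frequency_mhz=frequency_mhz,
        metabolites=mets,
        comp_met=np.array(comp_met),
        comp_group=np.array(comp_group),
        comp_offset=np.array(comp_offset),
        comp_weight=np.array(comp_weight),
        n_groups=group_counter,
        options=options,
    )


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------


class _ParamLayout:
    """Full parameter vector layout with a fixed mask (lb == ub)."""

    def __init__(self, model: FitModel):
        opts = model.options
        n_m, n_g, n_x = model.n_mets, model.n_groups, len(model.extra_singlets)
        self.n_widths = n_g if opts.width_per_group else n_m
        self.sl_area = slice(0, n_m)
        self.sl_center = slice(n_m, n_m + n_g)
        self.sl_width = slice(n_m + n_g, n_m + n_g + self.n_widths)
        nb = opts.baseline_order + 1
        base0 = n_m + n_g + self.n_widths
        self.sl_base = slice(base0, base0 + nb)
        x0 = base0 + nb
        self.sl_xarea = slice(x0, x0 + n_x)
        self.sl_xcenter = slice(x0 + n_x, x0 + 2 * n_x)
        self.sl_xwidth = slice(x0 + 2 * n_x, x0 + 3 * n_x)
        self.n_params = x0 + 3 * n_x

        w_def = opts.default_fwhm_hz / model.frequency_mhz
        w_lo, w_hi = (b / model.frequency_mhz for b in opts.fwhm_bounds_hz)
        lb = np.full(self.n_params, -np.inf)
        ub = np.full(self.n_params, np.inf)
        lb[self.sl_area] = 0.0
        centers = np.concatenate([m.group_centers for m in model.metabolites])
        mob = np.concatenate([m.group_mobility for m in model.metabolites])
        if opts.fix_centers:
            mob = np.zeros_like(mob)
        lb[self.sl_center] = centers - mob
        ub[self.sl_center] = centers + mob
        if opts.fix_widths:
            lb[self.sl_width] = ub[self.sl_width] = w_def
        else:
            lb[self.sl_width] = w_lo
            ub[self.sl_width] = w_hi
        lb[self.sl_xarea] = 0.0
        for k, (c0, _a0) in enumerate(model.extra_singlets):
            lb[self.sl_xcenter][k] = c0 - opts.extra_center_slack_ppm
            ub[self.sl_xcenter][k] = c0 + opts.extra_center_slack_ppm
            lb[self.sl_xwidth][k] = w_lo
            ub[self.sl_xwidth][k] = w_hi
        # np slicing of lb/ub above returns views, so the writes stuck
        self.lb, self.ub = lb, ub
        self.fixed = lb == ub
        self.centers0, self.w_def = centers, w_def

    def initial(self, model: FitModel) -> np.ndarray:
        p = np.zeros(self.n_params)
        p[self.sl_center] = self.centers0
        p[self.sl_width] = self.w_def
        p[self.sl_xwidth] = self.w_def
        p[self.sl_xcenter] = [c0 for c0, _ in model.extra_singlets]
        p[self.sl_xarea] = [a0 for _, a0 in model.extra_singlets]
        return p


def _eval_model(params, model: FitModel, layout: _ParamLayout, x: np.ndarray,
                tnorm: np.ndarray) -> np.ndarray:
    areas = params[layout.sl_area]
    centers = params[layout.sl_center]
    widths = params[layout.sl_width]
    if model.options.width_per_group:
        comp_fwhm = widths[model.comp_group]
    else:
        comp_fwhm = widths[model.comp_met]
    comp_center = centers[model.comp_group] + model.comp_offset
    comp_area = areas[model.comp_met] * model.comp_weight
    u = 2.0 * (x[:, None] - comp_center[None, :]) / comp_fwhm[None, :]
    y = ((2.0 / math.pi) * comp_area / comp_fwhm / (1.0 + u * u)).sum(axis=1)
    for k in range(len(model.extra_singlets)):
        y += lorentzian(
            x,
            params[layout.sl_xcenter][k],
            params[layout.sl_xarea][k],
            params[layout.sl_xwidth][k],
        )
    y += np.polynomial.polynomial.polyval(tnorm, params[layout.sl_base])
    return y


def _linear_area_init(model, layout, params, x, tnorm, y):
    """Stage-one start: non-negative linear LS for areas (and baseline) with
    centres and widths frozen at their reference values."""
    n_m, n_x = model.n_mets, len(model.extra_singlets)
    nb = model.options.baseline_order + 1
    cols = []
    for mi in range(n_m):
        p = params.copy()
        p[layout.sl_area] = 0.0
        p[layout.sl_area][mi] = 1.0
        p[layout.sl_xarea] = 0.0
        p[layout.sl_base] = 0.0
        cols.append(_eval_model(p, model, layout, x, tnorm))
    for k in range(n_x):
        cols.append(
            lorentzian(x, params[layout.sl_xcenter][k], 1.0, params[layout.sl_xwidth][k])
        )
    for b in range(nb):
        cols.append(tnorm**b)
    a = np.column_stack(cols)
    lb = np.concatenate([np.zeros(n_m + n_x), np.full(nb, -np.inf)])
    ub = np.full(a.shape[1], np.inf)
    sol = lsq_linear(a, y, bounds=(lb, ub))
    out = params.copy()
    out[layout.sl_area] = sol.x[:n_m]
    out[layout.sl_xarea] = sol.x[n_m:n_m + n_x]
    out[layout.sl_base] = sol.x[n_m + n_x:]
    return out


def _robust_noise_sd(residual: np.ndarray) -> float:
    med = np.median(residual)
    return 1.4826 * np.median(np.abs(residual - med))


def fit(model: FitModel, spectrum: Spectrum, init: np.ndarray | None = None,
        options: CtlsOptions | None = None) -> FitResult:
    """Bound-constrained nonlinear least squares over the model window.

    Two-stage start: centres at reference shifts, width at the default, areas
    from a non-negative linear solve with the shape parameters frozen.
    Deterministic for a given ``(spectrum, model, options)``.
    """
    if options is not None:
        model = replace(model, options=options)
    opts = model.options
    high, low = model.window
    wz_lo, wz_hi = opts.water_zone
    if low >= wz_lo and high <= wz_hi:
        raise ValueError(f"window {model.window} lies inside the water-suppression zone")
    sl = spectrum.window_slice(high, low)
    x = spectrum.ppm[sl]
    y = spectrum.intensity[sl]
    if len(x) < 8:
        raise ValueError(f"window {model.window} not covered by spectrum")
    tnorm = (2.0 * x - (high + low)) / (high - low)

    layout = _ParamLayout(model)
    if init is None:
        params = _linear_area_init(model, layout, layout.initial(model), x, tnorm, y)
    else:
        params = np.asarray(init, dtype=float).copy()

    if opts.freeze_low_signal_factor > 0 and init is None:
        resid0 = y - _eval_model(params, model, layout, x, tnorm)
        noise0 = _robust_noise_sd(resid0)
        base0 = np.polynomial.polynomial.polyval(tnorm, params[layout.sl_base])
        detrended = y - base0
        span_by_group = np.zeros(model.n_groups)
        offs = np.abs(model.comp_offset)
        for ci, gi in enumerate(model.comp_group):
            span_by_group[gi] = max(span_by_group[gi], offs[ci])
        g0 = 0
        for mi, met in enumerate(model.metabolites):
            ng = len(met.group_centers)
            # tallest point near any of the metabolite's lines (allowing for
            # shift mobility); below the noise floor -> shape frozen
            hmax = 0.0
            for gj in range(ng):
                c = met.group_centers[gj]
                half = met.group_mobility[gj] + span_by_group[g0 + gj] + layout.w_def
                in_rng = (x <= c + half) & (x >= c - half)
                if in_rng.any():
                    hmax = max(hmax, float(np.max(detrended[in_rng])))
            if hmax < opts.freeze_low_signal_factor * noise0:
                gsl = slice(layout.sl_center.start + g0, layout.sl_center.start + g0 + ng)
                layout.lb[gsl] = layout.ub[gsl] = params[gsl]
                if opts.width_per_group:
                    wsl = slice(layout.sl_width.start + g0, layout.sl_width.start + g0 + ng)
                else:
                    wsl = slice(layout.sl_width.start + mi, layout.sl_width.start + mi + 1)
                layout.lb[wsl] = layout.ub[wsl] = params[wsl]
            g0 += ng
        layout.fixed = layout.lb == layout.ub

    free = ~layout.fixed
    if free.any():
        def resid(pfree):
            p = params.copy()
            p[free] = pfree
            return _eval_model(p, model, layout, x, tnorm) - y

        scale = max(float(np.max(np.abs(y))), 1.0)
        res = least_squares(
            resid,
            np.clip(params[free], layout.lb[free], layout.ub[free]),
            bounds=(layout.lb[free], layout.ub[free]),
            method="trf",
            xtol=opts.tol,
            ftol=opts.tol,
            gtol=opts.tol,
            max_nfev=opts.max_iter * max(1, free.sum()),
            x_scale="jac",
        )
        params[free] = res.x
        converged, nfev, message = res.status > 0, res.nfev, res.message
    else:  # fully constrained shape: the linear stage is the solution
        converged, nfev, message = True, 1, "linear solve (all shape parameters fixed)"

    fitted = _eval_model(params, model, layout, x, tnorm)
    residual = y - fitted
    areas, centers, widths, protons = {}, {}, {}, {}
    g0 = 0
    for mi, met in enumerate(model.metabolites):
        ng = len(met.group_centers)
        areas[met.name] = float(params[layout.sl_area][mi])
        centers[met.name] = params[layout.sl_center][g0:g0 + ng].copy()
        if opts.width_per_group:
            widths[met.name] = params[layout.sl_width][g0:g0 + ng].copy()
        else:
            widths[met.name] = float(params[layout.sl_width][mi])
        protons[met.name] = met.effective_protons
        g0 += ng
    extras = [
        (
            float(params[layout.sl_xcenter][k]),
            float(params[layout.sl_xarea][k]),
            float(params[layout.sl_xwidth][k]),
        )
        for k in range(len(model.extra_singlets))
    ]
    return FitResult(
        window=model.window,
        areas=areas,
        centers=centers,
        widths=widths,
        effective_protons=protons,
        baseline_coeffs=params[layout.sl_base].copy(),
        extra_singlets=extras,
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        noise_sd=_robust_noise_sd(residual),
        converged=bool(converged),
        n_evaluations=int(nfev),
        message=str(message),
    )


def detect_unidentified(model: FitModel, result: FitResult, spectrum: Spectrum,
                        threshold: float | None = None):
    """Add free singlets at residual peaks above ``threshold`` x robust noise
    SD and re-fit once. Peaks within 0.5 x FWHM of an already-modelled line
    are rejected; at most ``max_extra`` singlets are added.

    Returns ``(model, result)`` — unchanged when no peak qualifies.
    """
    opts = model.options
    threshold = opts.detect_threshold if threshold is None else threshold
    high, low = model.window
    sl = spectrum.window_slice(high, low)
    x = spectrum.ppm[sl]
    y = spectrum.intensity[sl]
    tnorm = (2.0 * x - (high + low)) / (high - low)

    # rebuild fitted curve from the result
    fitted = np.polynomial.polynomial.polyval(tnorm, result.baseline_coeffs)
    comp_centers = []
    fwhm_ref = opts.default_fwhm_hz / model.frequency_mhz
    g0 = 0
    for mi, met in enumerate(model.metabolites):
        w = result.widths[met.name]
        ws = w if np.ndim(w) else [w] * len(met.group_centers)
        area = result.areas[met.name]
        mask = model.comp_met == mi
        for cg, off, rw in zip(model.comp_group[mask], model.comp_offset[mask],
                               model.comp_weight[mask]):
            c = result.centers[met.name][cg - g0] + off
            wloc = ws[cg - g0] if np.ndim(w) else w
            fitted += lorentzian(x, c, area * rw, wloc)
            comp_centers.append((c, wloc))
        g0 += len(met.group_centers)
    for c, a, w in result.extra_singlets:
        fitted += lorentzian(x, c, a, w)
        comp_centers.append((c, w))

    residual = y - fitted
    noise = _robust_noise_sd(residual)
    if noise <= 0:
        noise = float(np.std(residual)) or 1.0
    is_peak = np.zeros(len(residual), dtype=bool)
    is_peak[1:-1] = (residual[1:-1] > residual[:-2]) & (residual[1:-1] >= residual[2:])
    is_peak &= residual > threshold * noise
    idx = np.flatnonzero(is_peak)
    idx = idx[np.argsort(residual[idx])[::-1]]
    added = []
    for i in idx:
        c = x[i]
        if any(abs(c - cc) < 0.5 * wloc for cc, wloc in comp_centers):
            continue
        # one singlet per resolvable feature: keep clear of accepted extras
        if any(abs(c - ca) < 2.0 * fwhm_ref for ca, _ in added):
            continue
        a0 = residual[i] * math.pi * fwhm_ref / 2.0
        added.append((float(c), float(a0)))
        if len(added) >= opts.max_extra:
            break
    if not added:
        return model, result
    new_model = replace(model, extra_singlets=list(model.extra_singlets) + added)
    return new_model, fit(new_model, spectrum)


def area_to_concentration(area: float, n_protons: int, tsp_area: float,
                          tsp_n_protons: int = 9,
                          tsp_conc_mmol_per_L: float = 0.5,
                          dilution: float = 700.0 / 630.0) -> float:
    """Absolute concentration (umol/L in the original urine) from a fitted
    area and the TSP reference area:

    ``c = (area/n) / (tsp_area/tsp_n) * tsp_conc_mmol * 1000 * dilution``.
    """
    if tsp_area <= 0:
        raise QCError("TSP reference area is non-positive: concentration reference lost")
    if n_protons < 1:
        raise ValueError("n_protons must be >= 1")
    per_proton = area / n_protons
    tsp_per_proton = tsp_area / tsp_n_protons
    return per_proton / tsp_per_proton * tsp_conc_mmol_per_L * 1000.0 * dilution


def load_window_plan(path=None) -> list:
    """Window plan as ``[(name, high_ppm, low_ppm), ...]``; packaged default
    when ``path`` is None."""
    path = path or packaged_data_path("windows.yaml")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [(w["name"], float(w["high_ppm"]), float(w["low_ppm"])) for w in doc["windows"]]


def quantify_sample(spectrum: Spectrum, signatures, window_plan=None,
                    options: CtlsOptions | None = None,
                    detect_extras: bool = False):
    """Quantify one spectrum window-by-window against the TSP reference.

    Returns ``(concentrations, results, flags)``: metabolite -> umol/L in
    the original urine, window name -> FitResult, and metabolite -> list of
    QC flags. Metabolites fitted in several windows get the proton-weighted
    mean of the per-window estimates.
    """
    options = options or CtlsOptions()
    window_plan = window_plan or load_window_plan()
    plan = {name: (hi, lo) for name, hi, lo in window_plan}
    if "tsp" not in plan:
        raise ValueError("window plan must contain a 'tsp' reference window")

    results: dict = {}
    tsp_model = build_fit_model([TSP_SIGNATURE], plan["tsp"], spectrum.frequency_mhz, options)
    tsp_res = fit(tsp_model, spectrum)
    results["tsp"] = tsp_res
    tsp_area = tsp_res.areas["tsp"]
    # reference must stand clearly above the local noise floor
    w = tsp_res.widths["tsp"]
    tsp_fwhm = float(np.atleast_1d(w)[0])
    tsp_height = 2.0 * tsp_area / (math.pi * tsp_fwhm)
    if tsp_area <= 0 or tsp_height < 10.0 * max(tsp_res.noise_sd, 1e-300):
        raise QCError("TSP reference signal missing or too weak")

    sig_by_name = {s.name: s for s in signatures}
    est_num: dict = {}
    est_den: dict = {}
    flags: dict = {name: [] for name in sig_by_name}
    lo_z, hi_z = options.suppression_flag_zone
    try:
        for name, (hi, lo) in plan.items():
            if name == "tsp":
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    model = build_fit_model(list(sig_by_name.values()), (hi, lo),
                                            spectrum.frequency_mhz, options)
                except ValueError:
                    continue  # no packaged signature in this window
            res = fit(model, spectrum)
            if detect_extras:
                model, res = detect_unidentified(model, res, spectrum)
            results[name] = res
            if not res.converged:
                for met in res.areas:
                    flags[met].append(f"non_converged:{name}")
                continue
            for met, area in res.areas.items():
                n_p = res.effective_protons[met]
                conc = area_to_concentration(
                    area, n_p, tsp_area,
                    tsp_conc_mmol_per_L=options.tsp_conc_mmol_per_L,
                    dilution=options.dilution,
                )
                est_num[met] = est_num.get(met, 0.0) + conc * n_p
                est_den[met] = est_den.get(met, 0) + n_p
    except (ValueError, QCError) as exc:
        raise type(exc)(f"window {name!r}: {exc}") from exc

    concentrations = {met: est_num[met] / est_den[met] for met in est_num}
    for name, sig in sig_by_name.items():
        if name in concentrations and any(
            lo_z <= g.center_ppm <= hi_z for g in sig.groups
        ):
            flags[name].append("suppression_affected")
    return concentrations, results, flags
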