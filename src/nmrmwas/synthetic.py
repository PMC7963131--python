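"""Synthetic multi-cohort serum NMR data with known ground truth.

The generator emulates the study design of a multi-cohort atherosclerosis
metabolome-wide association study: per-cohort sample tables with
demographics and cardiovascular risk factors, zero-inflated coronary artery
calcium (Agatston) and log-normal intima-media thickness outcomes, incident
event follow-up, and high-resolution 1H spectra in which each metabolite
contributes a block of near-perfectly correlated Lorentzian features plus a
broad macromolecule baseline (attenuated in the CPMG variant).

All randomness flows from one master seed through named substreams
(concentrations, baseline, noise, phenotypes, events), so the standard-1D
and CPMG variants of the same cohort share concentrations and noise and the
CPMG spectrum differs from the standard one exactly by the attenuation of
the broad baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .spectra import SpectrumSet
from .templates import (
    DEFAULT_BASELINE,
    BaselineComponent,
    MetaboliteTemplate,
)

# fixed substream labels -> offsets mixed into the master seed
_STREAMS = {"concentrations": 1, "baseline": 2, "noise": 3,
            "phenotypes": 4, "events": 5, "fid": 6, "graph": 7}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of a master seed; stable across runs."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


@dataclass(frozen=True)
class GridSpec:
    """The ppm grid spectra are synthesized on (ascending)."""

    ppm_min: float = 0.5
    ppm_max: float = 9.5
    n_points: int = 32768
    spectrometer_frequency: float = 600.13  # MHz

    def axis(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort."""

    cohort_name: str
    n_samples: int
    ethnicity_mix: dict = field(default_factory=lambda: {"european": 1.0})
    age_mean_sd: tuple[float, float] = (62.0, 10.0)
    cac_zero_probability: float = 0.4
    cac_lognormal_params: tuple[float, float] = (4.0, 1.4)   # of ln(CAC+1) | CAC>0
    imt_lognormal_params: tuple[float, float] = (-0.28, 0.18)  # of ln(IMT/mm)
    baseline_amplitude: float = 1.0
    cpmg_attenuation: float = 0.1
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if abs(sum(self.ethnicity_mix.values()) - 1.0) > 1e-9:
            raise ValueError("ethnicity proportions must sum to 1")
        if not (0.0 <= self.cac_zero_probability <= 1.0):
            raise ValueError("cac_zero_probability must be in [0,1]")
        if not (0.0 <= self.cpmg_attenuation <= 1.0):
            raise ValueError("cpmg_attenuation must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _lorentz(ppm: np.ndarray, center: float, hwhm_ppm: float) -> np.ndarray:
    # unit-height Lorentzian
    return hwhm_ppm ** 2 / ((ppm - center) ** 2 + hwhm_ppm ** 2)


def template_signature(t: MetaboliteTemplate, grid: GridSpec) -> np.ndarray:
    """Spectral signature of one metabolite at unit concentration."""
    ppm = grid.axis()
    sig = np.zeros_like(ppm)
    for pk in t.peaks:
        hwhm_ppm = (1.0 / (math.pi * pk.t2_s)) / 2.0 / grid.spectrometer_frequency
        for off_hz, inten in zip(pk.line_offsets_hz, pk.line_intensities):
            center = pk.center_ppm + off_hz / grid.spectrometer_frequency
            sig += inten * _lorentz(ppm, center, hwhm_ppm)
    return sig


def template_feature_blocks(
    templates: list[MetaboliteTemplate], grid: GridSpec, pad_fwhm: float = 2.0
) -> list[list[tuple[int, int]]]:
    """Per template, the index ranges (inclusive) covered by each multiplet."""
    ppm = grid.axis()
    out = []
    for t in templates:
        blocks = []
        for pk in t.peaks:
            fwhm_ppm = (1.0 / (math.pi * pk.t2_s)) / grid.spectrometer_frequency
            lo_ppm = pk.center_ppm + min(pk.line_offsets_hz) / grid.spectrometer_frequency - pad_fwhm * fwhm_ppm
            hi_ppm = pk.center_ppm + max(pk.line_offsets_hz) / grid.spectrometer_frequency + pad_fwhm * fwhm_ppm
            lo = int(np.searchsorted(ppm, lo_ppm, side="left"))
            hi = int(np.searchsorted(ppm, hi_ppm, side="right") - 1)
            blocks.append((max(lo, 0), min(hi, grid.n_points - 1)))
        out.append(blocks)
    return out


# covariate slopes used when building outcomes (per SD of age, male sex)
_AGE_BETA_CAC = 0.35
_SEX_BETA_CAC = 0.30
_AGE_BETA_IMT = 0.030
_AGE_LOGHR_PER_YEAR = 0.04
_BASE_HAZARD = 0.011          # events / person-year at the reference profile
_CENSOR_WINDOW = (8.0, 12.0)  # years of administrative follow-up


def generate_cohort(
    spec: CohortSpec,
    templates: list[MetaboliteTemplate],
    assay: str = "standard1d",
    grid: GridSpec | None = None,
    baseline_components: tuple[BaselineComponent, ...] = DEFAULT_BASELINE,
    phase_labels: tuple[str, str] = ("P1", "P2"),
) -> tuple[SpectrumSet, pd.DataFrame, pd.DataFrame]:
    """Generate one cohort: spectra, phenotype table, and ground truth.

    Returns
    -------
    spectra : SpectrumSet
    phenotypes : DataFrame, one row per sample
    ground_truth : DataFrame, one row per template with the planted effects
        and the feature index blocks of its multiplets
    """
    if assay not in ("standard1d", "cpmg"):
        raise ValueError("assay must be 'standard1d' or 'cpmg'")
    if not templates:
        raise ValueError("at least one metabolite template is required")
    grid = grid or GridSpec()
    any_effect = any(
        t.effect_on_cac or t.effect_on_imt or t.log_hazard_ratio for t in templates
    )
    if spec.noise_sd == 0 and not any_effect:
        raise ValueError(
            "degenerate configuration: zero spectral noise with no planted effects"
        )
    for t in templates:
        t.validate_window(grid.ppm_min, grid.ppm_max)

    n, m = spec.n_samples, len(templates)

    # --- concentrations (shared by both assays) -------------------------
    rng_c = substream(spec.seed, "concentrations")
    log_c = np.column_stack([
        rng_c.normal(t.mean_log_concentration, t.sd_log_concentration, size=n)
        for t in templates
    ])
    z = np.column_stack([
        (log_c[:, j] - templates[j].mean_log_concentration) / templates[j].sd_log_concentration
        for j in range(m)
    ])
    conc = np.exp(log_c)

    # --- spectra --------------------------------------------------------
    signatures = np.vstack([template_signature(t, grid) for t in templates])
    spectra = conc @ signatures

    rng_b = substream(spec.seed, "baseline")
    base_sig = np.vstack([
        c.relative_amplitude * _lorentz(
            grid.axis(), c.center_ppm,
            (1.0 / (math.pi * c.t2_s)) / 2.0 / grid.spectrometer_frequency)
        for c in baseline_components
    ])
    base_amp = spec.baseline_amplitude * np.exp(
        rng_b.normal(0.0, 0.2, size=(n, len(baseline_components))))
    atten = spec.cpmg_attenuation if assay == "cpmg" else 1.0
    spectra = spectra + atten * (base_amp @ base_sig)

    rng_n = substream(spec.seed, "noise")
    if spec.noise_sd > 0:
        spectra = spectra + rng_n.normal(0.0, spec.noise_sd, size=spectra.shape)

    # --- phenotypes -----------------------------------------------------
    rng_p = substream(spec.seed, "phenotypes")
    age_mean, age_sd = spec.age_mean_sd
    age = rng_p.normal(age_mean, age_sd, size=n).clip(30.0, 95.0)
    z_age = (age - age_mean) / age_sd
    sex = np.where(rng_p.random(n) < 0.5, "M", "F")
    eth_names = list(spec.ethnicity_mix)
    ethnicity = rng_p.choice(eth_names, size=n, p=[spec.ethnicity_mix[k] for k in eth_names])
    phase = np.where(rng_p.random(n) < 0.5, phase_labels[0], phase_labels[1])

    ldl = rng_p.normal(117.0, 31.0, size=n).clip(40, 300)
    hdl = rng_p.normal(51.0, 15.0, size=n).clip(15, 130)
    sbp = rng_p.normal(126.0, 20.0, size=n).clip(80, 230)
    smoking = rng_p.choice(["never", "past", "current"], size=n, p=[0.47, 0.40, 0.13])
    diabetes = (rng_p.random(n) < 0.12).astype(int)
    lipid_treatment = (rng_p.random(n) < 0.16).astype(int)
    bp_treatment = (rng_p.random(n) < 0.33).astype(int)

    beta_cac = np.array([t.effect_on_cac for t in templates])
    beta_imt = np.array([t.effect_on_imt for t in templates])
    eta_cac = z @ beta_cac + _AGE_BETA_CAC * z_age + _SEX_BETA_CAC * (sex == "M")
    eta_imt = z @ beta_imt + _AGE_BETA_IMT * z_age

    mu_cac, sd_cac = spec.cac_lognormal_params
    positive = rng_p.random(n) >= spec.cac_zero_probability
    ln_cac1 = np.where(
        positive,
        np.maximum(mu_cac + eta_cac + rng_p.normal(0.0, sd_cac, size=n), 1e-3),
        0.0,
    )
    cac = np.expm1(ln_cac1)

    mu_imt, sd_imt = spec.imt_lognormal_params
    log10_imt = mu_imt / math.log(10) + eta_imt + rng_p.normal(
        0.0, sd_imt / math.log(10), size=n)
    imt = 10.0 ** log10_imt

    # --- incident events ------------------------------------------------
    rng_e = substream(spec.seed, "events")
    log_hr = np.array([t.log_hazard_ratio for t in templates])
    lam = _BASE_HAZARD * np.exp(z @ log_hr + _AGE_LOGHR_PER_YEAR * (age - age_mean))
    t_event = rng_e.exponential(1.0 / lam)
    censor = rng_e.uniform(*_CENSOR_WINDOW, size=n)
    event_status = (t_event <= censor).astype(int)
    followup = np.minimum(t_event, censor)

    sample_ids = [f"{spec.cohort_name}_{i:05d}" for i in range(n)]
    pheno = pd.DataFrame({
        "sample_id": sample_ids,
        "cohort": spec.cohort_name,
        "phase": phase,
        "age": age,
        "sex": sex,
        "ethnicity": ethnicity,
        "cac_agatston": cac,
        "imt_mm": imt,
        "ln_cac1": ln_cac1,
        "log10_imt": log10_imt,
        "ldl": ldl,
        "hdl": hdl,
        "sbp": sbp,
        "smoking": smoking,
        "diabetes": diabetes,
        "lipid_treatment": lipid_treatment,
        "bp_treatment": bp_treatment,
        "event_status": event_status,
        "followup_time": followup,
    })

    blocks = template_feature_blocks(templates, grid)
    ppm_axis = grid.axis()
    truth = pd.DataFrame({
        "metabolite": [t.name for t in templates],
        "kegg_id": [t.kegg_id or "" for t in templates],
        "effect_on_cac": beta_cac,
        "effect_on_imt": beta_imt,
        "log_hazard_ratio": log_hr,
        "peak_ppms": [";".join(f"{pk.center_ppm:.4f}" for pk in t.peaks) for t in templates],
        "feature_blocks": [";".join(f"{lo}-{hi}" for lo, hi in b) for b in blocks],
        "sentinel_block_center": [int((b[0][0] + b[0][1]) // 2) for b in blocks],
    })

    sset = SpectrumSet(
        spectra, ppm_axis, assay, sample_ids,
        cohort=[spec.cohort_name] * n, phase=list(phase),
    )
    return sset, pheno, truth


# ----------------------------------------------------------------------
# time-domain synthesis


@dataclass(frozen=True)
class Acquisition:
    """Time-domain acquisition settings for FID synthesis."""

    dwell_time: float            # seconds per complex point
    n_points: int                # complex points; power of two
    spectrometer_frequency: float = 600.13  # MHz
    carrier_ppm: float = 4.7     # transmitter offset (centre of the window)

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.n_points < 2 or (self.n_points & (self.n_points - 1)) != 0:
            raise ValueError("n_points must be a power of two")

    @property
    def spectral_width_hz(self) -> float:
        return 1.0 / self.dwell_time


def generate_fid(
    concentrations: dict[str, float],
    templates: list[MetaboliteTemplate],
    acquisition: Acquisition,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthesize a free induction decay for one sample.

    The FID is a sum of exponentially decaying complex sinusoids — one per
    multiplet line, decay rate 1/T2 — scaled by the metabolite
    concentrations, plus complex white noise.  Returns an
    :class:`nmrmwas.processing.FID`.
    """
    from .processing import FID  # local import to avoid a cycle

    acq = acquisition
    t = np.arange(acq.n_points) * acq.dwell_time
    fid = np.zeros(acq.n_points, dtype=complex)
    nyquist = acq.spectral_width_hz / 2.0
    for tmpl in templates:
        c = concentrations.get(tmpl.name, 0.0)
        if c == 0.0:
            continue
        for pk in tmpl.peaks:
            if pk.t2_s <= 0:
                raise ValueError("non-positive T2")
            for off_hz, inten in zip(pk.line_offsets_hz, pk.line_intensities):
                f = (pk.center_ppm - acq.carrier_ppm) * acq.spectrometer_frequency + off_hz
                if abs(f) > nyquist:
                    raise ValueError(
                        f"line at {f:.1f} Hz outside spectral width "
                        f"±{nyquist:.1f} Hz")
                fid += c * inten * np.exp(2j * math.pi * f * t - t / pk.t2_s)
    if noise_sd > 0:
        rng = substream(seed, "fid")
        fid += noise_sd * (rng.standard_normal(acq.n_points)
                           + 1j * rng.standard_normal(acq.n_points))
    return FID(
        complex_points=fid,
        dwell_time=acq.dwell_time,
        spectrometer_frequency=acq.spectrometer_frequency,
        carrier_ppm=acq.carrier_ppm,
    )


# ----------------------------------------------------------------------
# toy reaction-pair graphs


def generate_reaction_graph(n_compounds: int, edge_density: float, seed: int = 0) -> nx.Graph:
    """Random undirected simple graph of compound nodes (KEGG-style labels).

    Each of the n(n-1)/2 possible edges is included independently with
    probability `edge_density`; reproducible from the seed.
    """
    if n_compounds < 2:
        raise ValueError("need at least 2 compounds")
    if not (0.0 < edge_density <= 1.0):
        raise ValueError("edge_density must be in (0, 1]")
    rng = substream(seed, "graph")
    labels = [f"C{i + 1:05d}" for i in range(n_compounds)]
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(n_compounds):
        for j in range(i + 1, n_compounds):
            if rng.random() < edge_density:
                g.add_edge(labels[i], labels[j])
    return g
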