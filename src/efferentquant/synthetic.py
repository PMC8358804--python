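"""Synthetic ABR waveforms, cochlear surface fields, and whole studies with
known ground truth.

The generator emulates the structure of a temporary-threshold-shift study in
the rat so that every downstream stage (threshold calling, segmentation,
densitometry, group statistics) can be tested against a truth it cannot see:

* **ABR series** — one averaged record per stimulus level (10-90 dB SPL in
  10-dB steps).  Each wave is a biphasic transient (negative trough
  preceding positive peak) so the standard peak-to-peak amplitude and
  positive-peak latency definitions apply.  Levels below the true threshold
  contain only noise; above it, wave amplitude grows linearly with level and
  latency shortens.  The 1000-sweep average is simulated directly as i.i.d.
  Gaussian noise per sample: statistically identical to averaging 1000
  sweeps and a few thousand times cheaper.

* **Cochlear fields** — 8-bit dark-on-light (DAB-like) frames of the OHC
  band with non-touching elliptical terminal buttons whose area follows a
  Gaussian cochleotopic profile over log-frequency peaking at 11.3 kHz in
  the sham condition, plus optional free immune cells in two classes:
  large (10-20 µm) immunoreactive macrophages rendered dark and small
  (5-10 µm) monocytes rendered at background contrast only.  A wavy band of
  immunoreactive efferent fiber fascicles runs along one edge of the frame,
  spatially disjoint from the buttons.  The band matters for densitometry
  realism: the field z-normalisation cancels any gray-scale change shared
  by the whole scene, so on a pure buttons-on-background image the
  normalised OD would measure only the stained-area fraction, not staining
  intensity.  Terminal depletion spares the passing fascicles, and that
  stable structure is what lets field-normalised button OD track the
  terminals' ChAT content.

* **Whole studies** — per-animal ABR series at each protocol day and
  per-frequency fields at each animal's terminal day, with group x day
  effects (threshold means, button area/OD scaling, immune-cell rates)
  injected as configuration.  Default effect sizes follow the printed group
  means of the study design this emulates (sham constant 10 dB; trauma
  day-13 mean 30 dB SD 6.32; stimulated-then-traumatised day-12 mean
  33.33 dB SD 5.16, back to baseline at day 13; area/OD ratios from the
  published correlation table); all are config, not constants.

Everything is reproducible: one integer seed, bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .abr import ABRSeries, Waveform
from .quant import ImageFrame

__all__ = [
    "ABRSimConfig",
    "CochleaSimConfig",
    "SizeProfile",
    "ODProfile",
    "StudyDesign",
    "ABRGroundTruth",
    "FrameGroundTruth",
    "StudyDataset",
    "GenerationError",
    "simulate_abr_series",
    "simulate_cochlea_image",
    "simulate_study",
    "default_threshold_effects",
    "default_icc_effects",
    "default_immune_rates",
    "ANALYSIS_FREQUENCIES_KHZ",
]

#: The six standard per-cochlea analysis frequencies (kHz).
ANALYSIS_FREQUENCIES_KHZ = (2.8, 8.0, 11.3, 16.0, 32.0, 45.2)


class GenerationError(RuntimeError):
    """Raised when a frame cannot host the requested objects without overlap."""


# --------------------------------------------------------------------------
# ABR simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ABRSimConfig:
    """Configuration of one simulated ABR level series.

    Latencies are absolute (from stimulus onset, so they already include the
    closed-field conduction delay) and specified at 90 dB; they stretch by
    ``latency_level_slope`` ms per dB of attenuation.  The rendered
    peak-to-peak amplitude of the full complex at level L >= threshold is
    ``amplitude_growth * (L - true_threshold + level step)`` µV, i.e. the
    first responding level already carries one step's worth of growth.
    """

    sampling_rate_per_ms: float = 24.4  # ~24.4 kHz digitisation
    record_duration_ms: float = 10.0
    stimulus_levels_db: tuple = tuple(range(10, 91, 10))
    true_threshold_db: float = 30.0
    conduction_delay_ms: float = 1.4
    wave_latencies_ms: tuple = (1.9, 2.8, 3.6, 4.4)  # positive peaks at 90 dB
    wave_rel_amplitudes: tuple = (1.0, 0.8, 0.9, 0.6)
    latency_level_slope_ms_per_db: float = 0.01
    amplitude_growth_uv_per_db: float = 0.1
    wave_sigma_ms: float = 0.15
    noise_sd_uv: float = 0.15  # post-averaging background SD
    seed: int = 0

    def __post_init__(self) -> None:
        lv = np.asarray(self.stimulus_levels_db, dtype=float)
        if lv.size < 2 or np.any(np.diff(lv) <= 0):
            raise ValueError("stimulus levels must be strictly increasing")
        step = float(np.diff(lv).max())
        if not (lv[0] - step) <= self.true_threshold_db <= (lv[-1] + step):
            raise ValueError(
                "true threshold must lie within one level step of the grid"
            )
        if self.noise_sd_uv < 0:
            raise ValueError("noise SD must be non-negative")
        if self.conduction_delay_ms < 0:
            raise ValueError("conduction delay must be non-negative")
        if len(self.wave_latencies_ms) != len(self.wave_rel_amplitudes):
            raise ValueError("one relative amplitude per wave is required")

    @property
    def level_step_db(self) -> float:
        return float(np.diff(np.asarray(self.stimulus_levels_db, dtype=float)).max())


@dataclass(frozen=True)
class ABRGroundTruth:
    """Truth behind one simulated series."""

    true_threshold_db: float
    wave_latencies_by_level: dict  # level -> tuple of peak times (ms)
    wave_amplitudes_by_level: dict  # level -> tuple of p-p amplitudes (µV)


def _canonical_wave_shape():
    """Unit biphasic transient: trough preceding a positive peak at u = 0.

    Built once on a fine grid: a positive Gaussian lobe minus a leading
    negative lobe, shifted so the positive peak sits exactly at the nominal
    latency and scaled to unit peak-to-peak amplitude.
    """
    u = np.linspace(-8.0, 8.0, 16001)
    raw = np.exp(-0.5 * u**2) - 0.9 * np.exp(-0.5 * (u + 1.6) ** 2)
    u_peak = u[np.argmax(raw)]
    pp = raw.max() - raw.min()
    return u_peak, pp


_WAVE_U_PEAK, _WAVE_PP = _canonical_wave_shape()


def _wave_eval(t_ms: np.ndarray, tau_ms: float, sigma_ms: float) -> np.ndarray:
    u = (t_ms - tau_ms) / sigma_ms + _WAVE_U_PEAK
    raw = np.exp(-0.5 * u**2) - 0.9 * np.exp(-0.5 * (u + 1.6) ** 2)
    return raw / _WAVE_PP  # unit peak-to-peak, positive peak at tau_ms


def simulate_abr_series(config: ABRSimConfig, seed=None):
    """Render one ascending ABR series.

    Returns ``(ABRSeries, ABRGroundTruth)``.  ``seed`` overrides
    ``config.seed`` when given (used by the study generator to fan out).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(config.record_duration_ms * config.sampling_rate_per_ms)) + 1
    t = np.arange(n) / config.sampling_rate_per_ms
    wfs, lat_by_level, amp_by_level = {}, {}, {}
    for lv in config.stimulus_levels_db:
        v = rng.normal(0.0, config.noise_sd_uv, size=n) if config.noise_sd_uv > 0 else np.zeros(n)
        if lv >= config.true_threshold_db:
            amp = config.amplitude_growth_uv_per_db * (
                lv - config.true_threshold_db + config.level_step_db
            )
            lats, amps = [], []
            for tau90, rel in zip(config.wave_latencies_ms, config.wave_rel_amplitudes):
                tau = tau90 + config.latency_level_slope_ms_per_db * (90.0 - lv)
                a = amp * rel
                v = v + a * _wave_eval(t, tau, config.wave_sigma_ms)
                lats.append(tau)
                amps.append(a)
            lat_by_level[float(lv)] = tuple(lats)
            amp_by_level[float(lv)] = tuple(amps)
        wfs[float(lv)] = Waveform(time_ms=t, voltage_uv=v, level_db=float(lv))
    series = ABRSeries(waveforms=wfs)
    truth = ABRGroundTruth(
        true_threshold_db=float(config.true_threshold_db),
        wave_latencies_by_level=lat_by_level,
        wave_amplitudes_by_level=amp_by_level,
    )
    return series, truth


# --------------------------------------------------------------------------
# Cochlear field simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeProfile:
    """Gaussian cochleotopic mean-area profile over log2 frequency.

    mean_area(f) = floor + (peak - floor) * exp(-log2(f/peak_khz)^2 / (2 s^2))

    Defaults peak at 11.3 kHz, the sham-condition tonotopic maximum.
    """

    peak_khz: float = 11.3
    peak_area_um2: float = 10.5
    floor_area_um2: float = 5.5
    sigma_octaves: float = 0.75
    area_sd_um2: float = 1.8  # within-field button-to-button spread
    min_area_um2: float = 1.5

    def mean_area(self, f_khz: float) -> float:
        z = np.log2(f_khz / self.peak_khz)
        g = np.exp(-0.5 * (z / self.sigma_octaves) ** 2)
        return self.floor_area_um2 + (self.peak_area_um2 - self.floor_area_um2) * g

    def scaled(self, factor: float) -> "SizeProfile":
        return replace(
            self,
            peak_area_um2=self.peak_area_um2 * factor,
            floor_area_um2=self.floor_area_um2 * factor,
        )


@dataclass(frozen=True)
class ODProfile:
    """Mean button optical density by frequency (flat by default, matching
    the sham condition's frequency-indifferent OD distribution)."""

    base_od: float = 0.55
    od_sd: float = 0.08

    def mean_od(self, f_khz: float) -> float:
        return self.base_od

    def scaled(self, factor: float) -> "ODProfile":
        return replace(self, base_od=self.base_od * factor)


@dataclass(frozen=True)
class CochleaSimConfig:
    """Configuration for simulated fields of the OHC band."""

    cochlea_length_um: float = 9400.0
    pixel_pitch_um: float = 0.2  # 25 pixels / µm²
    frame_size_px: tuple = (560, 560)  # 112 x 112 µm at default pitch
    size_profile: SizeProfile = field(default_factory=SizeProfile)
    od_profile: ODProfile = field(default_factory=ODProfile)
    button_density_per_10k_um2: float = 40.0
    macrophage_rate_per_1000um: float = 0.0
    monocyte_rate_per_1000um: float = 0.0
    macrophage_diameter_um: tuple = (12.0, 20.0)
    monocyte_diameter_um: tuple = (6.0, 10.0)
    macrophage_od: float = 0.90  # intense immunoreactivity
    monocyte_gray_offset: float = 35.0  # below background mean: faint contrast
    min_button_od: float = 0.30  # stained terminals are detectably dark
    background_gray: tuple = (200.0, 4.0)  # mean, SD
    # stable fascicle band along the bottom edge; not scaled by group effects.
    # Rendered much darker than any button so a single global density
    # threshold separates {band, buttons} from {cells, background} by gray
    # alone; the band is then rejected by the button area gate.
    fiber_band_fraction: float = 0.15
    fiber_band_od: float = 0.85
    fiber_band_gray_sd: float = 8.0
    fiber_band_wave_px: float = 6.0
    allow_overlap: bool = False
    circular_buttons: bool = False  # ellipses by default; disks for oracles
    max_place_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.button_density_per_10k_um2 < 0:
            raise ValueError("densities must be non-negative")
        if min(self.macrophage_rate_per_1000um, self.monocyte_rate_per_1000um) < 0:
            raise ValueError("immune-cell rates must be non-negative")
        if self.size_profile.floor_area_um2 <= 0 or self.size_profile.peak_area_um2 <= 0:
            raise ValueError("size profile must be strictly positive")

    @property
    def frame_area_um2(self) -> float:
        r, c = self.frame_size_px
        return r * c * self.pixel_pitch_um**2

    @property
    def frame_width_um(self) -> float:
        return self.frame_size_px[1] * self.pixel_pitch_um


@dataclass
class FrameGroundTruth:
    """Every object rendered into one frame."""

    frequency_khz: float
    buttons: list  # dicts: center_px, area_um2 (drawn), pixel_count, gray, od
    macrophages: list  # dicts: center_px, diameter_um, gray
    monocytes: list

    @property
    def n_buttons(self) -> int:
        return len(self.buttons)

    @property
    def n_macrophages(self) -> int:
        return len(self.macrophages)

    @property
    def n_monocytes(self) -> int:
        return len(self.monocytes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "frequency_khz": self.frequency_khz,
                "buttons": self.buttons,
                "macrophages": self.macrophages,
                "monocytes": self.monocytes,
            }
        )


def _place_objects(rng, shape, radii_px, existing, allow_overlap, max_tries, y_max=None):
    """Rejection-sample non-touching centers for objects of given radii."""
    placed = []
    occupied = list(existing)
    rows, cols = shape
    y_lim = rows if y_max is None else y_max
    for r in radii_px:
        ok = False
        if y_lim - r - 1 <= r + 1:
            raise GenerationError("objects do not fit above the fascicle band")
        for _ in range(max_tries):
            cy = rng.uniform(r + 1, y_lim - r - 1)
            cx = rng.uniform(r + 1, cols - r - 1)
            if allow_overlap or all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + 2.0) ** 2
                for oy, ox, orad in occupied
            ):
                ok = True
                break
        if not ok:
            raise GenerationError(
                "could not place all objects without overlap; frame too small "
                "for the requested density"
            )
        placed.append((cy, cx, r))
        occupied.append((cy, cx, r))
    return placed


def simulate_cochlea_image(config: CochleaSimConfig, frequency_khz: float, seed=None):
    """Render one OHC-band field at one frequency place.

    Returns ``(ImageFrame, FrameGroundTruth)``.  Buttons are dark ellipses
    with per-button gray drawn from the OD profile; immune cells are disks.
    Objects are non-touching unless ``allow_overlap`` is set, so the
    ground-truth count is unambiguous at pixel level.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, cols = config.frame_size_px
    pitch = config.pixel_pitch_um
    bg_mean, bg_sd = config.background_gray

    img = rng.normal(bg_mean, bg_sd, size=(rows, cols))

    # --- fascicle band: connected wavy stripe along the bottom edge ----
    band_top_min = rows
    if config.fiber_band_fraction > 0:
        band_gray = float(np.clip(255.0 * 10.0 ** (-config.fiber_band_od), 1.0, 254.0))
        x = np.arange(cols)
        phase = rng.uniform(0, 2 * np.pi)
        top = rows * (1.0 - config.fiber_band_fraction) + config.fiber_band_wave_px * np.sin(
            2 * np.pi * x / max(cols / 4.0, 1.0) + phase
        )
        rr_grid = np.arange(rows)[:, None]
        band_mask = rr_grid >= top[None, :]
        img[band_mask] = band_gray + rng.normal(
            0.0, config.fiber_band_gray_sd, size=int(band_mask.sum())
        )
        band_top_min = int(np.floor(top.min()))

    # --- terminal buttons ---------------------------------------------
    usable_frac = max(band_top_min, 0) / rows
    lam = (
        config.button_density_per_10k_um2
        * config.frame_area_um2
        * usable_frac
        / 10_000.0
    )
    n_buttons = int(rng.poisson(lam))
    prof = config.size_profile
    areas = rng.normal(prof.mean_area(frequency_khz), prof.area_sd_um2, size=n_buttons)
    areas = np.clip(areas, prof.min_area_um2, None)
    radii = np.sqrt(areas / np.pi) / pitch  # equivalent radius in px
    # axis ratios drawn up front so placement can space by the major axis
    if config.circular_buttons:
        ratios = np.ones(n_buttons)
    else:
        ratios = rng.uniform(0.75, 1.0, size=n_buttons)
    major_radii = radii / np.sqrt(ratios)

    # --- immune cells --------------------------------------------------
    n_macro = int(rng.poisson(config.macrophage_rate_per_1000um * config.frame_width_um / 1000.0))
    n_mono = int(rng.poisson(config.monocyte_rate_per_1000um * config.frame_width_um / 1000.0))
    macro_d = rng.uniform(*config.macrophage_diameter_um, size=n_macro)
    mono_d = rng.uniform(*config.monocyte_diameter_um, size=n_mono)

    # place big objects first: easier packing; all above the fascicle band
    y_max = band_top_min - 3 if band_top_min < rows else None
    macro_r = macro_d / 2.0 / pitch
    mono_r = mono_d / 2.0 / pitch
    placed_macro = _place_objects(
        rng, (rows, cols), macro_r, [], config.allow_overlap,
        config.max_place_tries, y_max=y_max,
    )
    placed_mono = _place_objects(
        rng, (rows, cols), mono_r, placed_macro, config.allow_overlap,
        config.max_place_tries, y_max=y_max,
    )
    placed_btn = _place_objects(
        rng,
        (rows, cols),
        major_radii,
        placed_macro + placed_mono,
        config.allow_overlap,
        config.max_place_tries,
        y_max=y_max,
    )

    odp = config.od_profile
    truth_buttons = []
    for (cy, cx, _), r, q, area in zip(placed_btn, radii, ratios, areas):
        od = max(
            rng.normal(odp.mean_od(frequency_khz), odp.od_sd), config.min_button_od
        )
        gray = float(np.clip(255.0 * 10.0 ** (-od), 1.0, 254.0))
        if config.circular_buttons:
            ry = rx = r
            angle = 0.0
        else:
            ry, rx = r / np.sqrt(q), r * np.sqrt(q)  # area-preserving ellipse
            angle = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(rows, cols), rotation=angle)
        img[rr, cc] = gray
        truth_buttons.append(
            {
                "center_px": (float(cy), float(cx)),
                "area_um2": float(area),
                "pixel_count": int(rr.size),
                "gray": gray,
                "od": float(od),
            }
        )

    truth_macro = []
    for (cy, cx, r), d in zip(placed_macro, macro_d):
        gray = float(np.clip(255.0 * 10.0 ** (-config.macrophage_od), 1.0, 254.0))
        rr, cc = draw_ellipse(cy, cx, r, r, shape=(rows, cols))
        img[rr, cc] = gray
        truth_macro.append(
            {"center_px": (float(cy), float(cx)), "diameter_um": float(d), "gray": gray}
        )

    truth_mono = []
    for (cy, cx, r), d in zip(placed_mono, mono_d):
        gray = float(np.clip(bg_mean - config.monocyte_gray_offset, 1.0, 254.0))
        rr, cc = draw_ellipse(cy, cx, r, r, shape=(rows, cols))
        img[rr, cc] = gray
        truth_mono.append(
            {"center_px": (float(cy), float(cx)), "diameter_um": float(d), "gray": gray}
        )

    frame = ImageFrame(
        # keep every pixel inside the 11-step calibration's dynamic range
        pixels=np.clip(np.round(img), 4, 255).astype(np.uint8),
        pixel_pitch_um=pitch,
        frequency_khz=float(frequency_khz),
    )
    truth = FrameGroundTruth(
        frequency_khz=float(frequency_khz),
        buttons=truth_buttons,
        macrophages=truth_macro,
        monocytes=truth_mono,
    )
    return frame, truth


# --------------------------------------------------------------------------
# Whole-study simulation
# --------------------------------------------------------------------------

PROTOCOL_DAYS = (0, 12, 13, 14, 19, 26)
_BASELINE_THR = (7.0, 1.5)  # true-threshold mean/SD in quiet (estimates land on 10 dB)


def default_threshold_effects(groups=("SC", "AT", "ES_AT")) -> dict:
    """(group, day) -> (mean, SD) of the true click threshold in dB SPL.

    Elevated cells follow the printed group means of the emulated design:
    trauma day 13 = 30 (SD 6.32), day 14 = 21.66 (4.08), day 19 = 13.33
    (5.16); stimulated groups peak at day 12 = 33.33 (5.16) and return to
    baseline at day 13.
    """
    eff = {}
    for g in groups:
        for d in PROTOCOL_DAYS:
            eff[(g, d)] = _BASELINE_THR
    if "AT" in groups:
        eff[("AT", 13)] = (30.0, 6.32)
        eff[("AT", 14)] = (21.66, 4.08)
        eff[("AT", 19)] = (13.33, 5.16)
    for g in ("ES", "ES_AT"):
        if g in groups:
            eff[(g, 12)] = (33.33, 5.16)
            eff[(g, 13)] = (8.0, 2.0)
            eff[(g, 14)] = (8.0, 2.0)
    return eff


def default_icc_effects(groups=("SC", "AT", "ES_AT")) -> dict:
    """(group, terminal day) -> (area scale, OD scale) relative to sham.

    Ratios follow the printed per-condition means relative to sham
    (area 8.14/9.11/11.36/11.33 vs 10.00; normalised OD 3.37/3.26/4.34/5.14
    vs 4.30): short-term depletion of size and OD after trauma, long-term
    rebound that is strongest for OD under prior cortical stimulation.
    """
    eff = {}
    for g in groups:
        for d in (13, 14, 26):
            eff[(g, d)] = (1.0, 1.0)
    if "AT" in groups:
        eff[("AT", 13)] = (0.814, 0.784)
        eff[("AT", 26)] = (1.136, 1.009)
    if "ES_AT" in groups:
        eff[("ES_AT", 13)] = (0.911, 0.758)
        eff[("ES_AT", 26)] = (1.133, 1.195)
    return eff


def default_immune_rates(groups=("SC", "AT", "ES_AT")) -> dict:
    """(group, terminal day) -> (macrophages, monocytes) per 1,000 µm.

    Qualitative pattern: inflammation peaks one day after trauma, is smaller
    under prior cortical stimulation, and subsides by day 26.
    """
    eff = {}
    for g in groups:
        for d in (13, 14, 26):
            eff[(g, d)] = (0.2, 0.3)
    if "AT" in groups:
        eff[("AT", 13)] = (1.5, 1.0)
        eff[("AT", 26)] = (0.5, 0.4)
    if "ES_AT" in groups:
        eff[("ES_AT", 13)] = (0.8, 0.6)
        eff[("ES_AT", 26)] = (0.3, 0.3)
    return eff


VALID_GROUPS = ("SC", "ES", "AT", "ES_AT")


@dataclass(frozen=True)
class StudyDesign:
    """Group structure and injected effects of one simulated study."""

    groups: tuple = ("SC", "AT", "ES_AT")
    n_per_group: int = 6
    timepoints: tuple = PROTOCOL_DAYS
    threshold_effects: dict | None = None  # (group, day) -> (mean, sd) dB
    icc_effects: dict | None = None  # (group, terminal day) -> (area, od) scales
    immune_rates: dict | None = None  # (group, terminal day) -> (macro, mono)
    terminal_days: dict | None = None  # group -> tuple of candidate days
    frequencies_khz: tuple = ANALYSIS_FREQUENCIES_KHZ
    abr: ABRSimConfig = field(default_factory=ABRSimConfig)
    cochlea: CochleaSimConfig = field(default_factory=CochleaSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in VALID_GROUPS:
                raise ValueError(f"unknown group label {g!r}")
        if self.n_per_group < 2:
            raise ValueError("need at least two animals per group")
        thr = self.threshold_effects or default_threshold_effects(self.groups)
        for g in self.groups:
            for d in self.timepoints:
                if (g, d) not in thr:
                    raise ValueError(f"threshold effect missing for {(g, d)}")
        object.__setattr__(self, "threshold_effects", thr)
        object.__setattr__(
            self, "icc_effects", self.icc_effects or default_icc_effects(self.groups)
        )
        object.__setattr__(
            self, "immune_rates", self.immune_rates or default_immune_rates(self.groups)
        )
        term = self.terminal_days or {
            g: ((13, 26) if g in ("AT", "ES_AT") else (26,)) for g in self.groups
        }
        object.__setattr__(self, "terminal_days", term)


@dataclass
class StudyDataset:
    """Everything one simulated study produced, plus its ground truth."""

    design: StudyDesign
    animals: pd.DataFrame  # animal, group, terminal_day
    true_thresholds: pd.DataFrame  # animal, group, timepoint_day, true_threshold_db
    abr_series: dict  # (animal, day) -> ABRSeries
    frames: dict  # (animal, frequency_khz) -> ImageFrame
    frame_truth: dict  # (animal, frequency_khz) -> FrameGroundTruth
    seed: int


def simulate_study(design: StudyDesign, seed=None) -> StudyDataset:
    """Simulate a full study: ABR series at every protocol day for every
    animal and per-frequency OHC fields at each animal's terminal day."""
    root = np.random.default_rng(design.seed if seed is None else seed)
    ss = np.random.SeedSequence(int(root.integers(0, 2**31 - 1)))
    animal_rows, thr_rows = [], []
    abr_series, frames, frame_truth = {}, {}, {}
    children = iter(ss.spawn(len(design.groups) * design.n_per_group))
    for g in design.groups:
        term_cycle = design.terminal_days[g]
        for i in range(design.n_per_group):
            animal = f"{g}_{i + 1:02d}"
            terminal = term_cycle[i % len(term_cycle)]
            animal_rows.append({"animal": animal, "group": g, "terminal_day": terminal})
            arng = np.random.default_rng(next(children))
            for day in design.timepoints:
                mu, sd = design.threshold_effects[(g, day)]
                thr = float(arng.normal(mu, sd))
                lv = np.asarray(design.abr.stimulus_levels_db, dtype=float)
                step = design.abr.level_step_db
                thr = float(np.clip(thr, lv[0] - step, lv[-1] + step))
                cfg = replace(design.abr, true_threshold_db=thr)
                series, _ = simulate_abr_series(
                    cfg, seed=int(arng.integers(0, 2**31 - 1))
                )
                series.meta.update(animal=animal, group=g, timepoint_day=day)
                abr_series[(animal, day)] = series
                thr_rows.append(
                    {
                        "animal": animal,
                        "group": g,
                        "timepoint_day": day,
                        "true_threshold_db": thr,
                    }
                )
            area_scale, od_scale = design.icc_effects[(g, terminal)]
            macro, mono = design.immune_rates[(g, terminal)]
            ccfg = replace(
                design.cochlea,
                size_profile=design.cochlea.size_profile.scaled(area_scale),
                od_profile=design.cochlea.od_profile.scaled(od_scale),
                macrophage_rate_per_1000um=macro,
                monocyte_rate_per_1000um=mono,
            )
            for f in design.frequencies_khz:
                fr, tr = simulate_cochlea_image(
                    ccfg, f, seed=int(arng.integers(0, 2**31 - 1))
                )
                frames[(animal, f)] = fr
                frame_truth[(animal, f)] = tr
    return StudyDataset(
        design=design,
        animals=pd.DataFrame(animal_rows),
        true_thresholds=pd.DataFrame(thr_rows),
        abr_series=abr_series,
        frames=frames,
        frame_truth=frame_truth,
        seed=design.seed if seed is None else seed,
    )
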