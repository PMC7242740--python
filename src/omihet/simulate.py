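"""Synthetic data generators for the OMI analysis pipeline.

Two families of inputs are produced here:

* TCSPC fluorescence-lifetime image stacks: per-pixel photon-arrival
  histograms following a two-exponential decay convolved with a Gaussian
  instrument response function (IRF), observed under Poisson counting noise,
  together with ground-truth label masks and parameter tables.

* Hierarchical single-cell endpoint cohorts: cells nested in organoids nested
  in patients, with planted variance components, treatment shifts expressed
  in control-SD units, and optional treated-arm mixture subpopulations.

All randomness flows from a single explicit seed through one
``numpy.random.Generator``; fixed seed implies bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NADPH = "nadph"
FAD = "fad"
CHANNELS = (NADPH, FAD)

#: canonical order of the three OMI endpoints in cohort simulations
ENDPOINTS = ("redox_ratio", "nadph_tau_m", "fad_tau_m")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# decay-level simulation
# ---------------------------------------------------------------------------

def generate_irf(
    fwhm: float,
    n_bins: int = 256,
    bin_width: float = 0.039,
    peak_offset_frac: float = 0.1,
) -> np.ndarray:
    """Discrete Gaussian instrument response function on the TCSPC time grid.

    Parameters
    ----------
    fwhm
        Full width at half maximum of the IRF, in ns.
    n_bins
        Number of time bins (>= 16).
    bin_width
        Width of one time bin, in ns.
    peak_offset_frac
        Position of the IRF peak as a fraction of the full time window.

    Returns
    -------
    Unit-sum kernel of length ``n_bins``.  In the ``fwhm -> 0`` limit the
    kernel degenerates to a single unit spike at the offset bin.
    """
    if fwhm <= 0:
        raise ValueError(f"IRF fwhm must be positive, got {fwhm}")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if n_bins < 16:
        raise ValueError(f"n_bins must be >= 16, got {n_bins}")
    t = np.arange(n_bins) * bin_width
    center = peak_offset_frac * n_bins * bin_width
    sigma = fwhm * _FWHM_TO_SIGMA
    with np.errstate(under="ignore"):
        kernel = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    total = kernel.sum()
    if total == 0.0 or not np.isfinite(total):
        # delta-function limit: all mass in the bin nearest the peak
        kernel = np.zeros(n_bins)
        kernel[int(np.argmin(np.abs(t - center)))] = 1.0
        return kernel
    return kernel / total


def decay_model(
    tau1: float,
    tau2: float,
    alpha1_frac: float,
    irf: np.ndarray,
    bin_width: float,
) -> np.ndarray:
    """IRF-convolved two-exponential decay shape on the bin grid (unit scale).

    The pure decay ``a1 exp(-t/tau1) + a2 exp(-t/tau2)`` is convolved with the
    IRF by discrete convolution truncated to the time window; both signals
    share bin 0 as the time origin.
    """
    n = irf.shape[0]
    t = np.arange(n) * bin_width
    pure = alpha1_frac * np.exp(-t / tau1) + (1.0 - alpha1_frac) * np.exp(-t / tau2)
    return np.convolve(irf, pure)[:n]


def simulate_decay(
    tau1: float,
    tau2: float,
    alpha1_frac: float,
    total_photons: float,
    background_rate: float,
    irf: np.ndarray,
    bin_width: float,
    rng: np.random.Generator | int | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Simulate one TCSPC photon-count histogram.

    The decay component is scaled so that its expected in-window sum equals
    ``total_photons``; ``background_rate`` counts per bin are added uniformly.
    With ``noise=True`` the returned histogram is a Poisson draw from the
    expectation, otherwise the expectation itself.
    """
    if not tau1 < tau2:
        raise ValueError(f"require tau1 < tau2, got tau1={tau1}, tau2={tau2}")
    if tau1 <= 0:
        raise ValueError("lifetimes must be positive")
    if not 0.0 <= alpha1_frac <= 1.0:
        raise ValueError(f"alpha1_frac must lie in [0, 1], got {alpha1_frac}")
    if total_photons < 0:
        raise ValueError("total_photons must be non-negative")
    if background_rate < 0:
        raise ValueError("background_rate must be non-negative")
    shape = decay_model(tau1, tau2, alpha1_frac, irf, bin_width)
    expected = total_photons * shape / shape.sum() + background_rate
    if not noise:
        return expected
    rng = np.random.default_rng(rng)
    return rng.poisson(expected).astype(np.int64)


# ---------------------------------------------------------------------------
# image-level simulation
# ---------------------------------------------------------------------------

@dataclass
class ChannelTruth:
    """Ground-truth two-exponential parameters of one cell in one channel."""

    tau1: float
    tau2: float
    alpha1_frac: float
    total_photons: float

    @property
    def tau_m(self) -> float:
        return self.alpha1_frac * self.tau1 + (1.0 - self.alpha1_frac) * self.tau2


@dataclass
class CellGeometry:
    """Disc (or annulus, when hollow) cell footprint in pixel coordinates."""

    center: tuple[float, float]  # (row, col)
    radius: float
    hollow: bool = False
    lumen_frac: float = 0.5  # lumen radius as a fraction of the cell radius
    truth: dict[str, ChannelTruth] = field(default_factory=dict)


@dataclass
class FlimSimSpec:
    """Specification of a synthetic FLIM field of view (both channels)."""

    image_width: int = 64
    image_height: int = 64
    n_time_bins: int = 256
    bin_width: float = 0.039  # ns; 256 bins cover ~10 ns
    irf_fwhm: float = 0.25  # ns
    background_rate: float = 0.05  # counts per bin per pixel
    cells: list[CellGeometry] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        window = self.n_time_bins * self.bin_width
        for cell in self.cells:
            for channel, tr in cell.truth.items():
                if channel not in CHANNELS:
                    raise ValueError(f"unknown channel {channel!r}")
                if not tr.tau1 < tr.tau2:
                    raise ValueError("require tau1 < tau2 in every channel")
                if not 0.0 <= tr.alpha1_frac <= 1.0:
                    raise ValueError("alpha1_frac must lie in [0, 1]")
                if tr.total_photons < 0:
                    raise ValueError("total_photons must be non-negative")
                if window < 3.0 * tr.tau2:
                    raise ValueError(
                        "time window must cover at least 3 x tau2 "
                        f"({window:.2f} ns < 3 x {tr.tau2:.2f} ns)"
                    )


def default_cell_truth(
    nadph_photons: float = 5000.0, fad_photons: float = 5000.0
) -> dict[str, ChannelTruth]:
    """Literature-typical free/bound lifetimes for the two co-enzyme channels."""
    return {
        NADPH: ChannelTruth(tau1=0.4, tau2=2.5, alpha1_frac=0.75, total_photons=nadph_photons),
        FAD: ChannelTruth(tau1=0.3, tau2=2.0, alpha1_frac=0.65, total_photons=fad_photons),
    }


def generate_flim_stack(
    spec: FlimSimSpec, noise: bool = True
) -> tuple[dict[str, np.ndarray], np.ndarray, pd.DataFrame]:
    """Render a FLIM field of view from a :class:`FlimSimSpec`.

    Returns
    -------
    stacks
        ``{channel: (H, W, n_time_bins) int64 array}`` of photon counts.
    mask
        ``(H, W) uint16`` ground-truth label mask; 0 = background, cells
        labeled 1..k in list order (later cells overwrite earlier ones);
        lumen pixels of hollow cells are background (label 0).
    truth
        Per-cell, per-channel ground-truth parameter table including the
        amplitude-weighted mean lifetime ``tau_m``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w, nt = spec.image_height, spec.image_width, spec.n_time_bins
    irf = generate_irf(spec.irf_fwhm, nt, spec.bin_width)
    if not spec.cells:
        warnings.warn("empty cell list: generating pure-background stack", stacklevel=2)
    rows, cols = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.uint16)
    expected = {ch: np.full((h, w, nt), spec.background_rate) for ch in CHANNELS}
    records = []
    for label, cell in enumerate(spec.cells, start=1):
        r0, c0 = cell.center
        dist2 = (rows - r0) ** 2 + (cols - c0) ** 2
        inside = dist2 <= cell.radius**2
        if cell.hollow:
            lumen = dist2 <= (cell.lumen_frac * cell.radius) ** 2
            body = inside & ~lumen
        else:
            body = inside
        mask[inside] = 0  # later cells overwrite earlier ones entirely
        mask[body] = label
        for ch, tr in cell.truth.items():
            pixel_expected = simulate_decay(
                tr.tau1, tr.tau2, tr.alpha1_frac, tr.total_photons,
                0.0, irf, spec.bin_width, noise=False,
            )
            expected[ch][inside] = spec.background_rate  # reset lumen too
            expected[ch][body] = spec.background_rate + pixel_expected
            records.append(
                {
                    "cell_id": label,
                    "channel": ch,
                    "tau1": tr.tau1,
                    "tau2": tr.tau2,
                    "alpha1_frac": tr.alpha1_frac,
                    "total_photons": tr.total_photons,
                    "tau_m": tr.tau_m,
                    "hollow": cell.hollow,
                }
            )
    if spec.cells and mask.max() == 0:
        warnings.warn("no cell produced any labeled pixel", stacklevel=2)
    stacks = {}
    for ch in CHANNELS:
        if noise:
            stacks[ch] = rng.poisson(expected[ch]).astype(np.int64)
        else:
            stacks[ch] = expected[ch]
    truth = pd.DataFrame.from_records(
        records,
        columns=["cell_id", "channel", "tau1", "tau2", "alpha1_frac",
                 "total_photons", "tau_m", "hollow"],
    )
    return stacks, mask, truth


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

@dataclass
class MixtureComponent:
    """One treated-arm subpopulation: proportion, per-endpoint shift
    (control-SD units), and cell-noise SD multiplier."""

    proportion: float
    shift: tuple[float, float, float] | float = 0.0
    sd_multiplier: float = 1.0


@dataclass
class TreatmentSpec:
    """A treatment arm: a bulk shift per endpoint in control-SD units, or an
    explicit mixture of subpopulations.

    ``organoid_sd_multiplier`` scales the between-organoid variability of the
    treated arm's organoids (a treatment that homogenizes the response
    contracts heterogeneity at the organoid level as well as the cell level).
    """

    name: str
    shift: tuple[float, float, float] | float = 0.0
    mixture: list[MixtureComponent] | None = None
    organoid_sd_multiplier: float = 1.0


@dataclass
class CohortSimSpec:
    """Hierarchical single-cell endpoint cohort: cells in organoids in patients.

    Endpoint order everywhere is ``(redox_ratio, nadph_tau_m, fad_tau_m)``.
    Variances are additive on the endpoint scale; treatment shifts are
    expressed in units of the control between+within SD,
    ``sqrt(var_organoid + var_cell)``.
    """

    n_patients: int = 2
    organoids_per_patient: int = 3
    cells_per_organoid: int = 50
    patient_means: tuple[float, float, float] = (1.0, 1.1, 1.2)
    patient_mean_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    var_organoid: tuple[float, float, float] = (0.003, 0.003, 0.003)
    var_cell: tuple[float, float, float] = (0.01, 0.01, 0.01)
    treatments: list[TreatmentSpec] = field(default_factory=list)
    timepoint_h: float = 72.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.organoids_per_patient, self.cells_per_organoid) < 1:
            raise ValueError("cohort dimensions must be >= 1")
        if any(v < 0 for v in self.var_organoid) or any(v < 0 for v in self.var_cell):
            raise ValueError("variances must be non-negative")
        if any(m <= 0 for m in self.patient_means[1:]):
            raise ValueError("lifetimes must be positive")
        for tr in self.treatments:
            if tr.name == "control":
                raise ValueError("'control' is reserved for the untreated arm")
            if tr.mixture is not None:
                total = sum(c.proportion for c in tr.mixture)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"mixture proportions must sum to 1, got {total}")


def _as_shift_vector(shift) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(shift, dtype=float), (len(ENDPOINTS),))
    return np.array(arr, dtype=float)


def generate_cell_table(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a hierarchical single-cell endpoint table with ground-truth labels.

    Control cells follow ``patient_mean + Normal(0, var_organoid) +
    Normal(0, var_cell)`` per endpoint.  Treated arms get their own organoids
    (treated and control organoids are physically distinct cultures); treated
    cells are additionally shifted by ``shift x control SD`` or drawn from the
    given mixture of subpopulations.  ``true_component`` is 0 for control and
    bulk-shifted cells, 1-based for mixture components.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_e = len(ENDPOINTS)
    control_sd = np.sqrt(np.asarray(spec.var_organoid) + np.asarray(spec.var_cell))
    arms: list[TreatmentSpec] = [TreatmentSpec("control")] + list(spec.treatments)
    frames = []
    for p in range(spec.n_patients):
        patient = f"P{p + 1:02d}"
        p_mean = np.asarray(spec.patient_means, dtype=float) + rng.normal(
            0.0, spec.patient_mean_sd, size=n_e
        )
        organoid_counter = 0
        for arm in arms:
            for _ in range(spec.organoids_per_patient):
                organoid_counter += 1
                organoid = f"{patient}-O{organoid_counter:03d}"
                org_mult = getattr(arm, "organoid_sd_multiplier", 1.0)
                org_eff = rng.normal(0.0, org_mult * np.sqrt(spec.var_organoid), size=n_e)
                n_c = spec.cells_per_organoid
                cell_sd = np.sqrt(np.asarray(spec.var_cell))
                base = p_mean + org_eff
                if arm.mixture is None:
                    shift = _as_shift_vector(arm.shift) * control_sd
                    values = base + shift + rng.normal(0.0, cell_sd, size=(n_c, n_e))
                    component = np.zeros(n_c, dtype=int)
                else:
                    props = np.array([c.proportion for c in arm.mixture])
                    component = rng.choice(len(arm.mixture), size=n_c, p=props) + 1
                    values = np.empty((n_c, n_e))
                    for k, comp in enumerate(arm.mixture, start=1):
                        sel = component == k
                        shift = _as_shift_vector(comp.shift) * control_sd
                        values[sel] = base + shift + rng.normal(
                            0.0, cell_sd * comp.sd_multiplier, size=(int(sel.sum()), n_e)
                        )
                frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": patient,
                            "organoid_id": organoid,
                            "cell_id": np.arange(1, n_c + 1),
                            "treatment": arm.name,
                            "timepoint_h": spec.timepoint_h,
                            "morphology": "unknown",
                            "redox_ratio_raw": values[:, 0],
                            "nadph_tau_m": values[:, 1],
                            "fad_tau_m": values[:, 2],
                            "true_component": component,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
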