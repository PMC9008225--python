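"""Binary-phase Fresnel holography for single-neuron photostimulation.

A ferroelectric SLM displays binary (0/pi) phase holograms built by
superposing laterally shifted Fresnel zone plates, one per target, and
binarizing the resulting phase either by thresholding or by bidirectional
(serpentine) Floyd-Steinberg error diffusion. A Keplerian telescope of
magnification beta demagnifies the SLM plane onto the sample, so a target
at sample coordinate (x, y) corresponds to a zone-plate centre at
(x, y)/beta on the SLM and a demagnified pixel of size beta * pixel_pitch.

A band-limited angular-spectrum propagator serves as the numerical
verification oracle: propagating the displayed hologram to the focal
distance must produce foci at the commanded positions. Gaussian focus
fitting, second-order polynomial sample->SLM calibration, and affine
(rotation/shift/scale) electrode-grid registration complete the
calibration chain of the optical system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SLMSpec",
    "Hologram",
    "FocusFit",
    "CalibrationFit",
    "AffineTransform",
    "fresnel_zone_plate",
    "synthesize_hologram",
    "min_focus_distance",
    "working_distance",
    "propagate",
    "focus_position_um",
    "fit_focus",
    "calibrate_mapping",
    "register_electrode_grids",
]


@dataclass(frozen=True)
class SLMSpec:
    """Spatial-light-modulator and relay-optics parameters.

    Defaults model a QXGA-class ferroelectric device: 1536 x 2048 pixels
    of 8.2 um pitch, 450 nm illumination, telescope magnification
    beta = 25/180 = 1/7.2, final lens focal length 25 mm, binary phase at
    up to 400 Hz.
    """

    n_rows: int = 1536
    n_cols: int = 2048
    pixel_pitch_um: float = 8.2
    wavelength_nm: float = 450.0
    beta: float = 25.0 / 180.0
    f3_m: float = 0.025
    max_refresh_hz: float = 400.0

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "pixel_pitch_um", "wavelength_nm",
                     "beta", "f3_m", "max_refresh_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pitch_m(self) -> float:
        return self.pixel_pitch_um * 1e-6

    @property
    def wavelength_m(self) -> float:
        return self.wavelength_nm * 1e-9

    @property
    def temporal_resolution_s(self) -> float:
        """Shortest hologram display interval, 1 / max refresh rate."""
        return 1.0 / self.max_refresh_hz

    def grid_m(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered pixel coordinate grids (x, y) in metres; the pixel at
        index (n_rows//2, n_cols//2) sits exactly on the optical axis."""
        x = (np.arange(self.n_cols) - self.n_cols // 2) * self.pitch_m
        y = (np.arange(self.n_rows) - self.n_rows // 2) * self.pitch_m
        return np.meshgrid(x, y)


@dataclass
class Hologram:
    """Binary phase field on the SLM grid, values in {0, pi}."""

    phase: np.ndarray
    targets_um: list[tuple[float, float]]
    focal_m: float
    method: str
    spec: SLMSpec

    def __post_init__(self) -> None:
        vals = np.unique(self.phase)
        if not np.all(np.isin(vals, [0.0, np.pi])):
            raise ValueError("binary hologram phase must be 0 or pi")
        if self.phase.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("phase dimensions must match the SLM grid")


def _check_sampling(spec: SLMSpec, f_m: float, shift_m: tuple[float, float] = (0.0, 0.0)) -> None:
    # adjacent-pixel phase step of the quadratic phase must stay below pi
    x, y = spec.grid_m()
    r_max = np.sqrt(
        (np.abs(x).max() + abs(shift_m[0])) ** 2
        + (np.abs(y).max() + abs(shift_m[1])) ** 2
    )
    step = 2 * np.pi * r_max * spec.pitch_m / (spec.wavelength_m * f_m)
    if step > np.pi:
        raise ValueError(
            f"focal distance {f_m * 1e3:.2f} mm aliases on this grid; "
            f"need f >= {2 * r_max * spec.pitch_m / spec.wavelength_m * 1e3:.2f} mm"
        )


def fresnel_zone_plate(
    f_m: float, spec: SLMSpec, center_m: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Continuous quadratic phase exp(i pi r^2 / (lambda f)) on the SLM grid.

    Returns the complex field; its phase at the centre pixel is zero.
    Raises when the adjacent-pixel phase step would exceed pi (aliasing).
    """
    if f_m <= 0:
        raise ValueError("focal distance must be positive")
    _check_sampling(spec, f_m, center_m)
    x, y = spec.grid_m()
    r2 = (x - center_m[0]) ** 2 + (y - center_m[1]) ** 2
    return np.exp(1j * np.pi * r2 / (spec.wavelength_m * f_m))


def _binarize_threshold(field: np.ndarray) -> np.ndarray:
    return np.where(field.real >= 0, 0.0, np.pi)


def _binarize_error_diffusion(field: np.ndarray) -> np.ndarray:
    """Bidirectional Floyd-Steinberg quantization of unit phasors to +-1."""
    mag = np.abs(field)
    work = np.where(mag > 0, field / np.where(mag > 0, mag, 1.0), 1.0 + 0.0j)
    work = work.astype(complex).copy()
    n_rows, n_cols = work.shape
    out = np.zeros(work.shape)
    for r in range(n_rows):
        forward = r % 2 == 0
        cols = range(n_cols) if forward else range(n_cols - 1, -1, -1)
        step = 1 if forward else -1
        for c in cols:
            v = work[r, c]
            q = 1.0 if v.real >= 0 else -1.0
            out[r, c] = 0.0 if q > 0 else np.pi
            err = v - q
            if 0 <= c + step < n_cols:
                work[r, c + step] += err * (7 / 16)
            if r + 1 < n_rows:
                if 0 <= c - step < n_cols:
                    work[r + 1, c - step] += err * (3 / 16)
                work[r + 1, c] += err * (5 / 16)
                if 0 <= c + step < n_cols:
                    work[r + 1, c + step] += err * (1 / 16)
    return out


def synthesize_hologram(
    targets_um: list[tuple[float, float]],
    f_m: float,
    spec: SLMSpec,
    method: str = "threshold",
) -> Hologram:
    """Multi-target binary hologram from superposed shifted zone plates.

    ``targets_um`` are sample-plane coordinates; each maps to an SLM-plane
    zone-plate centre at ``target / beta``. The complex superposition is
    binarized to {0, pi} either by phase thresholding or by bidirectional
    error diffusion (better focus-to-background for complex holograms).
    """
    if not targets_um:
        raise ValueError("target list is empty")
    if method not in ("threshold", "error_diffusion"):
        raise ValueError(f"unknown binarization method {method!r}")
    half_x = spec.n_cols // 2 * spec.pixel_pitch_um * spec.beta
    half_y = spec.n_rows // 2 * spec.pixel_pitch_um * spec.beta
    field = np.zeros((spec.n_rows, spec.n_cols), complex)
    for tx, ty in targets_um:
        if abs(tx) > half_x or abs(ty) > half_y:
            raise ValueError(f"target ({tx}, {ty}) um outside the addressable field")
        center = (tx * 1e-6 / spec.beta, ty * 1e-6 / spec.beta)
        field += fresnel_zone_plate(f_m, spec, center)
    phase = (
        _binarize_threshold(field)
        if method == "threshold"
        else _binarize_error_diffusion(field)
    )
    return Hologram(phase, [tuple(map(float, t)) for t in targets_um], f_m, method, spec)


def min_focus_distance(spec: SLMSpec) -> float:
    """Minimum focusing distance beta * N * pitch^2 / (2 lambda), metres,
    with N the pixel count along the shorter SLM side."""
    n_short = min(spec.n_rows, spec.n_cols)
    return spec.beta * n_short * spec.pitch_m**2 / (2 * spec.wavelength_m)


def working_distance(f_min_m: float, f3_m: float) -> float:
    """Overall working distance d_w = f_min + f_3."""
    if f_min_m < 0 or f3_m <= 0:
        raise ValueError("distances must be positive")
    return f_min_m + f3_m


# ---------------------------------------------------------------------------
# propagation oracle

def propagate(
    hologram: Hologram | np.ndarray,
    z_m: float,
    spec: SLMSpec,
    pad_factor: int = 2,
    band_limit: bool = True,
) -> np.ndarray:
    """Scalar-diffraction intensity at distance z via the band-limited
    angular-spectrum method on a zero-padded grid.

    Uniform unit-amplitude illumination of the phase hologram is assumed.
    Zero padding suppresses wrap-around; the Matsushima band limit
    suppresses aliasing of the transfer function at long distances.
    Energy within the propagating band is conserved.
    """
    if z_m <= 0:
        raise ValueError("propagation distance must be positive")
    phase = hologram.phase if isinstance(hologram, Hologram) else np.asarray(hologram)
    n_rows, n_cols = phase.shape
    u0 = np.exp(1j * phase)

    pr, pc = n_rows * pad_factor, n_cols * pad_factor
    u = np.zeros((pr, pc), complex)
    r0, c0 = (pr - n_rows) // 2, (pc - n_cols) // 2
    u[r0 : r0 + n_rows, c0 : c0 + n_cols] = u0

    lam = spec.wavelength_m
    fy = np.fft.fftfreq(pr, spec.pitch_m)[:, None]
    fx = np.fft.fftfreq(pc, spec.pitch_m)[None, :]
    arg = 1.0 / lam**2 - fx**2 - fy**2
    kz = 2 * np.pi * np.sqrt(np.maximum(arg, 0.0))
    h = np.where(arg > 0, np.exp(1j * kz * z_m), 0.0)
    if band_limit:
        dfx = 1.0 / (pc * spec.pitch_m)
        dfy = 1.0 / (pr * spec.pitch_m)
        fx_lim = 1.0 / (lam * np.sqrt((2 * dfx * z_m) ** 2 + 1.0))
        fy_lim = 1.0 / (lam * np.sqrt((2 * dfy * z_m) ** 2 + 1.0))
        h = h * ((np.abs(fx) <= fx_lim) & (np.abs(fy) <= fy_lim))

    uz = np.fft.ifft2(np.fft.fft2(u) * h)
    return np.abs(uz[r0 : r0 + n_rows, c0 : c0 + n_cols]) ** 2


def focus_position_um(
    intensity: np.ndarray, spec: SLMSpec, refine: int = 3
) -> tuple[float, float]:
    """Sample-plane (x, y) of the brightest focus, in um.

    Peak pixel refined by an intensity centroid over a small patch, then
    converted from SLM-plane to sample-plane coordinates via beta.
    """
    r, c = np.unravel_index(np.argmax(intensity), intensity.shape)
    r0, r1 = max(r - refine, 0), min(r + refine + 1, intensity.shape[0])
    c0, c1 = max(c - refine, 0), min(c + refine + 1, intensity.shape[1])
    patch = intensity[r0:r1, c0:c1]
    rr, cc = np.mgrid[r0:r1, c0:c1]
    total = patch.sum()
    rf = (rr * patch).sum() / total
    cf = (cc * patch).sum() / total
    x_slm = (cf - spec.n_cols // 2) * spec.pixel_pitch_um
    y_slm = (rf - spec.n_rows // 2) * spec.pixel_pitch_um
    return x_slm * spec.beta, y_slm * spec.beta


# ---------------------------------------------------------------------------
# focus fitting and calibration

@dataclass
class FocusFit:
    """2-D Gaussian fit of a focus image (pixel units)."""

    center_xy: tuple[float, float]
    sigma_xy: tuple[float, float]
    amplitude: float
    offset: float

    @property
    def fwhm_xy(self) -> tuple[float, float]:
        k = 2.0 * np.sqrt(2.0 * np.log(2.0))
        return (k * self.sigma_xy[0], k * self.sigma_xy[1])

    @property
    def one_over_e2_width_xy(self) -> tuple[float, float]:
        return (4.0 * self.sigma_xy[0], 4.0 * self.sigma_xy[1])


def _gauss2d(coords, amp, x0, y0, sx, sy, off):
    x, y = coords
    return (
        amp * np.exp(-(((x - x0) ** 2) / (2 * sx**2) + ((y - y0) ** 2) / (2 * sy**2)))
        + off
    ).ravel()


def fit_focus(image: np.ndarray) -> FocusFit:
    """Least-squares 2-D Gaussian fit of a single dominant focus."""
    img = np.asarray(image, float)
    ny, nx = img.shape
    y, x = np.mgrid[0:ny, 0:nx]
    off0 = float(np.median(img))
    amp0 = float(img.max() - off0)
    r0, c0 = np.unravel_index(np.argmax(img), img.shape)
    w = img - off0
    w = np.clip(w, 0, None)
    total = w.sum() or 1.0
    sx0 = float(np.sqrt((w * (x - c0) ** 2).sum() / total)) or 1.0
    sy0 = float(np.sqrt((w * (y - r0) ** 2).sum() / total)) or 1.0
    try:
        popt, _ = curve_fit(
            _gauss2d,
            (x, y),
            img.ravel(),
            p0=[amp0, c0, r0, max(sx0, 0.5), max(sy0, 0.5), off0],
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise ValueError("Gaussian focus fit did not converge") from exc
    amp, x0, y0, sx, sy, off = popt
    return FocusFit((float(x0), float(y0)), (abs(float(sx)), abs(float(sy))),
                    float(amp), float(off))


def _poly2_design(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x**2, x * y, y**2])


@dataclass
class CalibrationFit:
    """Second-order polynomial map from sample-plane to SLM-plane
    coordinates, with least-squares residuals."""

    coefficients: np.ndarray  # (2, 6): rows are x- and y-output coefficients
    residual_rms: float
    order: int = 2

    def predict(self, sample_points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(sample_points, float))
        return _poly2_design(pts) @ self.coefficients.T


def calibrate_mapping(
    sample_points: np.ndarray, slm_points: np.ndarray, order: int = 2
) -> CalibrationFit:
    """Fit the sample->SLM coordinate mapping with a 2nd-order 2-D polynomial.

    Requires at least 6 non-degenerate point pairs.
    """
    if order != 2:
        raise ValueError("only the second-order mapping is supported")
    sp = np.atleast_2d(np.asarray(sample_points, float))
    tp = np.atleast_2d(np.asarray(slm_points, float))
    if sp.shape != tp.shape or sp.shape[1] != 2:
        raise ValueError("point lists must be matched (n, 2) arrays")
    if sp.shape[0] < 6:
        raise ValueError("second-order calibration needs at least 6 point pairs")
    design = _poly2_design(sp)
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("degenerate (e.g. collinear) calibration points")
    coeffs, *_ = np.linalg.lstsq(design, tp, rcond=None)
    resid = design @ coeffs - tp
    rms = float(np.sqrt(np.mean(resid**2)))
    return CalibrationFit(coeffs.T, rms)


@dataclass
class AffineTransform:
    """Linear map plus offset: b = a @ matrix.T + offset."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residual_rms: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset, self.residual_rms)


def register_electrode_grids(
    centroids_a: np.ndarray, centroids_b: np.ndarray
) -> AffineTransform:
    """Least-squares affine registration of matched electrode centroids.

    Accounts for rotation, shift, and linear scaling between two images of
    the same electrode grid; needs >= 3 matched points.
    """
    a = np.atleast_2d(np.asarray(centroids_a, float))
    b = np.atleast_2d(np.asarray(centroids_b, float))
    if a.shape != b.shape or a.shape[1] != 2:
        raise ValueError("centroid lists must be matched (n, 2) arrays")
    if a.shape[0] < 3:
        raise ValueError("affine registration needs at least 3 matched points")
    design = np.column_stack([a, np.ones(len(a))])
    sol, *_ = np.linalg.lstsq(design, b, rcond=None)
    matrix = sol[:2].T
    offset = sol[2]
    resid = design @ sol - b
    rms = float(np.sqrt(np.mean(resid**2)))
    return AffineTransform(matrix, offset, rms)
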