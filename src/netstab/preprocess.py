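"""Temporal preprocessing of BOLD time series.

Everything that happens to a 4D resting-state series between spatial
alignment (out of scope here; inputs are assumed aligned) and metric
computation: dropping equilibration volumes, nuisance regression against a
Friston-24 motion expansion plus tissue signals, framewise-displacement
based motion screening and scrubbing, and band-pass filtering to the
canonical 0.01-0.1 Hz resting-state band.

The processing order mirrors standard resting-state practice: drop initial
volumes -> nuisance regression -> scrubbing, with the band-pass applied only
on the branch feeding ReHo / degree centrality / ROI connectivity (ALFF and
fALFF are spectral measures and consume the unfiltered residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BoldSeries",
    "MotionTable",
    "FDSeries",
    "drop_initial_volumes",
    "compute_fd",
    "screen_gross_motion",
    "build_friston24",
    "nuisance_regress",
    "scrub",
    "bandpass",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BoldSeries:
    """One subject-session 4D BOLD grid.

    Parameters
    ----------
    data:
        Array of shape ``(x, y, z, t)``; arbitrary signal units.
    tr_seconds:
        Sampling interval (repetition time) in seconds.
    affine:
        4x4 voxel-to-world matrix, carried opaquely for NIfTI round-trips.
    volume_kept:
        Boolean mask over the time axis. Starts all-true; scrubbing clears
        entries. Consumers must operate on kept frames only.
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    volume_kept: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t), got {self.data.ndim}D")
        if self.n_volumes < 2:
            raise ValueError("BOLD series needs at least 2 volumes")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.volume_kept is None:
            self.volume_kept = np.ones(self.n_volumes, dtype=bool)
        else:
            self.volume_kept = np.asarray(self.volume_kept, dtype=bool)
            if self.volume_kept.shape != (self.n_volumes,):
                raise ValueError("volume_kept length must equal number of volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_kept(self) -> int:
        return int(self.volume_kept.sum())

    def kept_data(self) -> np.ndarray:
        """Time-ordered concatenation of retained frames, shape (x,y,z,n_kept)."""
        return self.data[..., self.volume_kept]


@dataclass
class MotionTable:
    """Rigid-body realignment parameters: translations in mm, rotations in radians."""

    translations: np.ndarray  # (t, 3) mm
    rotations: np.ndarray     # (t, 3) radians

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=np.float64))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=np.float64))
        if self.translations.shape[1] != 3 or self.rotations.shape[1] != 3:
            raise ValueError("motion table needs 3 translation and 3 rotation columns")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ValueError("translation and rotation row counts differ")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Six-column (t, 6) array: translations then rotations."""
        return np.hstack([self.translations, self.rotations])

    def drop_initial(self, n: int) -> "MotionTable":
        """Truncate the first ``n`` rows, mirroring :func:`drop_initial_volumes`."""
        if n >= self.n_volumes:
            raise ValueError("cannot drop all motion rows")
        return MotionTable(self.translations[n:], self.rotations[n:])

    @classmethod
    def from_text(cls, path) -> "MotionTable":
        arr = np.loadtxt(path)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError(f"motion file {path} must have 6 whitespace-delimited columns")
        return cls(arr[:, :3], arr[:, 3:])


@dataclass
class FDSeries:
    """Per-volume framewise displacement (mm) and the scrubbing threshold."""

    fd: np.ndarray
    threshold_mm: float = 0.2

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=np.float64)
        if self.threshold_mm <= 0:
            raise ValueError("threshold_mm must be positive")
        if np.any(self.fd < 0) or not np.all(np.isfinite(self.fd)):
            raise ValueError("framewise displacement must be finite and nonnegative")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def drop_initial_volumes(series: BoldSeries, n: int = 10) -> BoldSeries:
    """Discard the first ``n`` (equilibration) volumes.

    Motion-table consumers must truncate identically via
    :meth:`MotionTable.drop_initial`.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= series.n_volumes:
        raise ValueError(
            f"cannot drop {n} volumes from a series of length {series.n_volumes}"
        )
    if n == 0:
        return series
    return BoldSeries(
        series.data[..., n:],
        series.tr_seconds,
        affine=series.affine,
        volume_kept=series.volume_kept[n:].copy(),
    )


def compute_fd(motion: MotionTable, head_radius_mm: float = 50.0) -> FDSeries:
    """Framewise displacement, Power convention.

    FD[i] = sum of absolute backward differences of the three translations
    (mm) plus ``head_radius_mm`` times the same for the three rotations
    (radians converted to arc length on a sphere of that radius). FD[0] = 0
    by convention.
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 motion rows to compute FD")
    if head_radius_mm <= 0:
        raise ValueError("head_radius_mm must be positive")
    params = motion.as_matrix()
    if not np.all(np.isfinite(params)):
        raise ValueError("motion parameters contain non-finite values")
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1) * head_radius_mm
    fd = np.concatenate([[0.0], dt + dr])
    return FDSeries(fd)


def screen_gross_motion(
    motion: MotionTable,
    trans_limit_mm: float = 1.5,
    rot_limit_deg: float = 1.5,
) -> tuple[bool, np.ndarray]:
    """Subject-level gross-motion screen.

    Fails when any translation exceeds ``trans_limit_mm`` (mm) or any
    rotation exceeds ``rot_limit_deg`` (degrees; stored radians are
    converted here). Returns ``(passed, offending_frame_indices)``.
    """
    trans_bad = np.abs(motion.translations) > trans_limit_mm
    rot_bad = np.abs(np.degrees(motion.rotations)) > rot_limit_deg
    offending = np.where(trans_bad.any(axis=1) | rot_bad.any(axis=1))[0]
    return offending.size == 0, offending


def build_friston24(motion: MotionTable) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Columns: the 6 realignment parameters, their one-volume-lagged copies
    (first row zero-filled), and the squares of both sets — (t, 24).
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 motion rows")
    p = motion.as_matrix()
    lagged = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lagged, p**2, lagged**2])


def _check_design_rank(design: np.ndarray) -> None:
    """Reject rank-deficient designs, naming the first collinear column.

    Column 0 is the intercept; reported indices refer to the caller's
    regressor matrix (0-based, intercept excluded).
    """
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    # greedy scan: first column linearly dependent on its predecessors
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(design[:, :j]):
            raise ValueError(
                f"nuisance design is rank-deficient: regressor column {j - 1} "
                "is collinear with earlier columns (or constant)"
            )
    raise ValueError("nuisance design is rank-deficient")


def nuisance_regress(series: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Residualize every voxel series against [intercept | regressors] by OLS.

    The intercept is always included, so residuals are mean-centred.
    Residuals are orthogonal to every regressor column.
    """
    regressors = np.asarray(regressors, dtype=np.float64)
    if regressors.ndim != 2:
        raise ValueError("regressors must be a 2D (t, k) matrix")
    t = series.n_volumes
    if regressors.shape[0] != t:
        raise ValueError(
            f"regressor rows ({regressors.shape[0]}) != series length ({t})"
        )
    if regressors.shape[1] >= t:
        raise ValueError("need fewer regressors than time points")
    if not np.all(np.isfinite(regressors)):
        raise ValueError("regressors contain non-finite values")

    design = np.hstack([np.ones((t, 1)), regressors])
    _check_design_rank(design)

    shape = series.data.shape
    y = series.data.reshape(-1, t).T            # (t, n_voxels)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return BoldSeries(
        resid.T.reshape(shape),
        series.tr_seconds,
        affine=series.affine,
        volume_kept=series.volume_kept.copy(),
    )


def scrub(series: BoldSeries, fd: FDSeries) -> tuple[BoldSeries, float]:
    """Motion scrubbing: drop every volume whose FD exceeds the threshold.

    Returns the series with ``volume_kept`` updated and the retained
    fraction. Downstream metrics see the kept frames concatenated in time
    order; no interpolation or imputation is performed.
    """
    if fd.fd.shape[0] != series.n_volumes:
        raise ValueError("FD length must equal series length")
    keep = series.volume_kept & (fd.fd <= fd.threshold_mm)
    retained = keep.sum() / series.n_volumes
    if retained == 0:
        raise ValueError("scrubbing removed every volume")
    out = BoldSeries(
        series.data,
        series.tr_seconds,
        affine=series.affine,
        volume_kept=keep,
    )
    return out, float(retained)


def bandpass(series: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> BoldSeries:
    """Zero-phase band-pass via a frequency-domain mask on the kept frames.

    Bins with ``low_hz <= f <= high_hz`` are retained at unit gain, all
    others (including DC) are zeroed, giving exact band edges with no
    filter-order choice. Scrub gaps are treated as a contiguous series.
    The returned series contains only the kept frames (all marked kept).
    """
    nyquist = 1.0 / (2.0 * series.tr_seconds)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyquist:.4g} Hz")

    data = series.kept_data()
    n = data.shape[3]
    freqs = np.fft.rfftfreq(n, d=series.tr_seconds)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    if not mask.any():
        raise ValueError(
            f"no frequency bin falls in [{low_hz}, {high_hz}] Hz for n={n}, "
            f"TR={series.tr_seconds}s (bin spacing {freqs[1]:.5f} Hz)"
        )
    spec = np.fft.rfft(data, axis=3)
    spec[..., ~mask] = 0.0
    filtered = np.fft.irfft(spec, n=n, axis=3)
    return BoldSeries(filtered, series.tr_seconds, affine=series.affine)
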