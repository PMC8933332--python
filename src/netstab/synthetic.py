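"""Synthetic two-session resting-state BOLD generator with known ground truth.

Emulates the acquisition this pipeline targets — two 15-minute sessions of
300 volumes at TR = 3 s, one week apart — on a desk-scale voxel grid, so
every downstream stage (preprocessing, voxel metrics, ROI connectivity,
stability statistics) can be tested end to end without downloading data.

Signal model, per subject:

* Fifteen spherical ROIs (DMN 4, CEN 4, SN 7) carry latent network signals
  built as random-phase sinusoid combs on the DFT frequency grid inside
  0.01-0.1 Hz (exact band control, no filter edge effects), correlated
  across ROIs through a Cholesky factor of a prescribed 15x15 correlation
  matrix. Every voxel of an ROI shares its ROI's latent, which keeps the
  degree-centrality ground truth interpretable.
* Non-ROI gray-matter voxels get independent in-band latents.
* A global out-of-band (0.11-0.16 Hz) nuisance signal loads weakly on gray
  matter and strongly on the white-matter and CSF compartments, so the
  tissue-mean nuisance regressors have something real to remove.
* Per-voxel amplitude scales are drawn uniformly from ``amplitude_range``
  once per subject and reused in both sessions — the subject's stable
  spatial fingerprint.
* White noise of ``noise_sd`` is added per session.
* Motion traces are slow random walks plus occasional one-frame spikes
  large enough to trip framewise-displacement scrubbing.

Session fidelity: every session-specific random process P (ROI latents,
voxel latents, nuisance signal, motion trace) is mixed as

    P_session = sqrt(f) * P_shared + sqrt(1 - f) * P_unique

so ``session_fidelity`` f is the fraction of session-level signal variance
shared between the two visits, and f = 1 with ``noise_sd`` = 0 makes the
sessions bit-identical — the exact perfect-stability limit. Randomness is
driven by one global integer seed; per-subject and per-purpose streams are
derived deterministically, and are independent of the fidelity value, so
runs at different fidelities with the same seed are paired draw-for-draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fixtures import generate_fixture_tables  # re-exported: packaged study tables
from .network import DEFAULT_ROI_NAMES, NETWORK_SIZES, NETWORKS, NetworkAtlas
from .preprocess import BoldSeries, MotionTable, compute_fd

__all__ = [
    "RoiSpec",
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "default_roi_layout",
    "default_connectivity",
    "generate_dataset",
    "write_dataset",
    "generate_fixture_tables",
]


@dataclass
class RoiSpec:
    """A spherical ROI: center voxel, radius in voxels, network label."""

    name: str
    network: str
    center: tuple[int, int, int]
    radius: float = 1.8

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape)
        d2 = sum((idx[a] - self.center[a]) ** 2 for a in range(3))
        return d2 <= self.radius**2


def default_roi_layout(grid_shape: tuple[int, int, int] = (16, 16, 10)) -> list[RoiSpec]:
    """Fifteen disjoint radius-1.8 spheres on a spacing-3 lattice.

    Radius 1.8 makes each sphere the full 3x3x3 cube (27 voxels); lattice
    spacing 3 keeps the cubes disjoint while letting them touch, so ReHo
    neighbourhoods straddle ROI boundaries as they would in real cortex.
    Centers stay inside the gray-matter slab (see :func:`generate_dataset`).
    """
    nx, ny, nz = grid_shape
    xs = [4, 7, 10]
    ys = [3, 6, 9, 12]
    zs = [2, 5, 8]
    if nx < 14 or ny < 15 or nz < 10:
        raise ValueError(f"grid {grid_shape} too small for the default ROI layout")
    centers = [(x, y, z) for z in zs for y in ys for x in xs][:15]
    names = [name for net in NETWORKS for name in DEFAULT_ROI_NAMES[net]]
    networks = [net for net in NETWORKS for _ in range(NETWORK_SIZES[net])]
    return [
        RoiSpec(name, net, center)
        for name, net, center in zip(names, networks, centers)
    ]


def default_connectivity(within: float = 0.5, between: float = 0.2) -> np.ndarray:
    """Block-structured 15x15 ROI correlation matrix.

    Correlation ``within`` inside each network block and ``between`` across
    networks. For 0 <= between <= within < 1 this is a sum of PSD pieces
    (between * all-ones + (within-between) * block-ones + (1-within) * I),
    hence guaranteed positive semidefinite with unit diagonal.
    """
    if not 0 <= between <= within < 1:
        raise ValueError("need 0 <= between <= within < 1")
    sizes = [NETWORK_SIZES[n] for n in NETWORKS]
    c = np.full((15, 15), between)
    start = 0
    for s in sizes:
        c[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-session study.

    Defaults mirror the emulated acquisition (300 volumes at TR 3 s, 16
    subjects) with a desk-scale 16x16x10 grid; ``session_fidelity`` 0.9
    lands the downstream stability in the strong range typical of
    well-behaved test-retest data.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 10)
    n_volumes: int = 300
    tr_seconds: float = 3.0
    n_subjects: int = 16
    session_fidelity: float = 0.9
    roi_layout: list[RoiSpec] = field(default_factory=default_roi_layout)
    latent_connectivity: np.ndarray = field(default_factory=default_connectivity)
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 0.4
    motion_spike_rate: float = 0.03
    spectral_shape: str = "flat"  # "flat" or "one_over_f" comb weighting
    seed: int = 0

    def __post_init__(self) -> None:
        self.latent_connectivity = np.asarray(self.latent_connectivity, dtype=np.float64)
        if len(self.grid_shape) != 3 or any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if self.n_volumes <= 0 or self.n_subjects <= 0:
            raise ValueError("n_volumes and n_subjects must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0.0 <= self.session_fidelity <= 1.0:
            raise ValueError("session_fidelity must lie in [0, 1]")
        if not 0.0 <= self.motion_spike_rate <= 1.0:
            raise ValueError("motion_spike_rate must lie in [0, 1]")
        if len(self.roi_layout) != 15:
            raise ValueError("roi_layout must define exactly 15 ROIs")
        lo, hi = self.amplitude_range
        if not 0 < lo <= hi:
            raise ValueError("amplitude_range must be positive with min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.spectral_shape not in {"flat", "one_over_f"}:
            raise ValueError("spectral_shape must be 'flat' or 'one_over_f'")
        c = self.latent_connectivity
        if c.shape != (15, 15):
            raise ValueError("latent_connectivity must be 15x15")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("latent_connectivity must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("latent_connectivity must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(c).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"latent_connectivity is not positive semidefinite: "
                f"smallest eigenvalue {eigmin:.3e}"
            )


@dataclass
class GroundTruth:
    """What the generator actually used, for parameter-recovery tests."""

    amplitude_maps: dict[str, np.ndarray]          # subject -> 3D map
    connectivity: np.ndarray                       # the 15x15 matrix used
    fidelity: float
    fd_series: dict[tuple[str, int], np.ndarray]   # (subject, session) -> FD (mm)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    subjects: list[str]
    bold: dict[tuple[str, int], BoldSeries]        # (subject, session 1|2)
    motion: dict[tuple[str, int], MotionTable]
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    atlas: NetworkAtlas
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _band_signals(
    rng: np.random.Generator,
    n_signals: int,
    n: int,
    tr: float,
    low_hz: float,
    high_hz: float,
    shape: str = "flat",
) -> np.ndarray:
    """Unit-variance signals as random-phase sinusoid combs in [low, high] Hz."""
    freqs = np.fft.rfftfreq(n, d=tr)
    band = (freqs >= low_hz) & (freqs <= high_hz)
    if not band.any():
        raise ValueError("no DFT bin inside the requested band")
    k = int(band.sum())
    if shape == "flat":
        amps = np.ones(k)
    else:  # 1/f comb
        amps = 1.0 / freqs[band]
    # complex-Gaussian bins: Rayleigh magnitudes, uniform phases — realized
    # spectra then vary between draws as real BOLD spectra do, instead of
    # every realization carrying the identical deterministic comb
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_signals, k))
    mags = rng.rayleigh(scale=np.sqrt(0.5), size=(n_signals, k))
    spec = np.zeros((n_signals, freqs.size), dtype=complex)
    spec[:, band] = amps * mags * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return x / sd


def _mix(f: float, shared: np.ndarray, unique: np.ndarray, normalize: bool = False) -> np.ndarray:
    """sqrt(f)*shared + sqrt(1-f)*unique, optionally renormalized to unit sd.

    The renormalization (used for signals, not motion) pins the realized
    variance: without it the shared-unique cross term inflates session
    variance by up to 2*sqrt(f(1-f))*corr(shared, unique), a spurious
    fidelity-dependent energy jitter that peaks at f = 0.5.
    """
    mixed = np.sqrt(f) * shared + np.sqrt(1.0 - f) * unique
    if normalize:
        sd = mixed.std(axis=-1, keepdims=True)
        mixed = mixed / np.where(sd > 0, sd, 1.0)
    return mixed


def _motion_trace(
    rng: np.random.Generator, n: int, spike_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Slow drift plus one-frame spikes; returns (translations, rotations)."""
    trans = np.cumsum(rng.normal(0.0, 0.01, size=(n, 3)), axis=0)
    rots = np.cumsum(rng.normal(0.0, 1e-4, size=(n, 3)), axis=0)
    spikes = rng.random(n) < spike_rate
    spikes[0] = False
    for t in np.where(spikes)[0]:
        axis = rng.integers(0, 6)
        sign = rng.choice([-1.0, 1.0])
        if axis < 3:
            trans[t, axis] += sign * rng.uniform(0.3, 0.6)
        else:
            rots[t, axis - 3] += sign * rng.uniform(0.006, 0.012)
    return trans, rots


def _tissue_masks(grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    """Brain = full grid; WM and CSF are slabs at the x extremes, GM between."""
    nx = grid_shape[0]
    brain = np.ones(grid_shape, dtype=bool)
    wm = np.zeros(grid_shape, dtype=bool)
    csf = np.zeros(grid_shape, dtype=bool)
    wm[: max(nx // 8, 1)] = True
    csf[nx - max(nx // 8, 1) :] = True
    gm = brain & ~wm & ~csf
    return brain, gm, wm, csf


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full two-session synthetic study described by ``spec``."""
    grid = spec.grid_shape
    n = spec.n_volumes
    f = spec.session_fidelity

    brain, gm, wm, csf = _tissue_masks(grid)

    roi_masks = [roi.mask(grid) for roi in spec.roi_layout]
    occupancy = np.zeros(grid, dtype=int)
    for roi, m in zip(spec.roi_layout, roi_masks):
        if not (m <= gm).all():
            raise ValueError(f"ROI {roi.name!r} leaves the gray-matter mask")
        occupancy += m
    if occupancy.max() > 1:
        raise ValueError("ROI masks overlap")
    atlas = NetworkAtlas(
        [(roi.name, roi.network, m) for roi, m in zip(spec.roi_layout, roi_masks)]
    )

    # Cholesky with a small diagonal jitter to absorb borderline-PSD inputs
    c = spec.latent_connectivity + 1e-8 * np.eye(15)
    chol = np.linalg.cholesky(c)

    roi_index = np.full(grid, -1, dtype=int)
    for i, m in enumerate(roi_masks):
        roi_index[m] = i
    free_gm = gm & (roi_index < 0)
    n_free = int(free_gm.sum())
    n_wmcsf = int((wm | csf).sum())

    subjects = [f"sub{i + 1:02d}" for i in range(spec.n_subjects)]
    bold: dict[tuple[str, int], BoldSeries] = {}
    motion: dict[tuple[str, int], MotionTable] = {}
    amp_maps: dict[str, np.ndarray] = {}
    fd_truth: dict[tuple[str, int], np.ndarray] = {}

    for si, subj in enumerate(subjects):
        def stream(tag: int, session: int = 0) -> np.random.Generator:
            # deterministic per (seed, subject, purpose, session); fidelity-free
            return np.random.default_rng([spec.seed, si, tag, session])

        amp = stream(0).uniform(*spec.amplitude_range, size=grid)
        amp_maps[subj] = amp
        # per-voxel out-of-band loadings: the subject's stable spatial
        # fingerprint of fractional band power (vascular/physiological
        # heterogeneity); shared across sessions like the amplitude map
        n_roi_vox = int((roi_index >= 0).sum())
        gm_load = stream(1).uniform(0.02, 0.11, size=n_free)
        roi_load = stream(1, 2).uniform(0.02, 0.11, size=n_roi_vox)
        tissue_load = stream(1, 1).uniform(0.6, 1.2, size=n_wmcsf)
        # stable partial coupling of each ROI voxel to its network latent:
        # within-region synchrony is high but not perfect, which is what
        # gives ReHo and DC their realistic session-to-session variation
        coupling = stream(1, 3).uniform(0.6, 0.95, size=n_roi_vox)

        def session_process(tag: int, builder, session: int):
            """Fidelity-mixed, unit-variance realization of one random process."""
            shared = builder(stream(tag, 0))
            unique = builder(stream(tag, session))
            return _mix(f, shared, unique, normalize=True)

        for sess in (1, 2):
            roi_latents = session_process(
                2,
                lambda rng: _band_signals(rng, 15, n, spec.tr_seconds, 0.01, 0.1,
                                          spec.spectral_shape),
                sess,
            )
            roi_latents = chol @ roi_latents
            voxel_latents = session_process(
                3,
                lambda rng: _band_signals(rng, n_free, n, spec.tr_seconds, 0.01, 0.1,
                                          spec.spectral_shape),
                sess,
            )
            # rows: global physiological signal, WM-specific, CSF-specific —
            # distinct components keep the two tissue-mean regressors
            # linearly independent even in the noise-free limit
            nuis_global, nuis_wm, nuis_csf = session_process(
                4,
                lambda rng: _band_signals(rng, 3, n, spec.tr_seconds, 0.11, 0.16),
                sess,
            )
            trans, rots = (
                _mix(f, a, b)
                for a, b in zip(
                    _motion_trace(stream(5, 0), n, spec.motion_spike_rate),
                    _motion_trace(stream(5, sess), n, spec.motion_spike_rate),
                )
            )

            roi_voxel_latents = session_process(
                7,
                lambda rng: _band_signals(rng, n_roi_vox, n, spec.tr_seconds,
                                          0.01, 0.1, spec.spectral_shape),
                sess,
            )

            data = np.zeros(grid + (n,))
            in_roi = roi_index >= 0
            data[in_roi] = amp[in_roi, None] * (
                coupling[:, None] * roi_latents[roi_index[in_roi]]
                + np.sqrt(1.0 - coupling[:, None] ** 2) * roi_voxel_latents
            )
            data[free_gm] = amp[free_gm, None] * voxel_latents
            data[free_gm] += gm_load[:, None] * nuis_global
            data[in_roi] += roi_load[:, None] * nuis_global
            tissue = np.empty((n_wmcsf, n))
            tissue[: int(wm.sum())] = 0.8 * nuis_global + 0.6 * nuis_wm
            tissue[int(wm.sum()) :] = 0.8 * nuis_global + 0.6 * nuis_csf
            data[wm | csf] = tissue_load[:, None] * tissue
            if spec.noise_sd > 0:
                data[brain] += stream(6, sess).normal(
                    0.0, spec.noise_sd, size=(int(brain.sum()), n)
                )

            bold[(subj, sess)] = BoldSeries(data, spec.tr_seconds)
            mt = MotionTable(trans, rots)
            motion[(subj, sess)] = mt
            fd_truth[(subj, sess)] = compute_fd(mt).fd

    truth = GroundTruth(
        amplitude_maps=amp_maps,
        connectivity=spec.latent_connectivity.copy(),
        fidelity=f,
        fd_series=fd_truth,
    )
    return SyntheticDataset(
        spec=spec,
        subjects=subjects,
        bold=bold,
        motion=motion,
        brain_mask=brain,
        gm_mask=gm,
        wm_mask=wm,
        csf_mask=csf,
        atlas=atlas,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write the dataset in standard formats.

    NIfTI-1 4D volumes per subject/session, 3D tissue masks, a
    tab-separated atlas manifest (roi_name, network, center, radius),
    whitespace-delimited 6-column motion text files, and the ground truth
    as one JSON file (arrays flattened with their shapes).
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    voxel_mm = 1.5  # emulated acquisition resolution
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])

    for name, mask in [
        ("brain_mask", dataset.brain_mask),
        ("gm_mask", dataset.gm_mask),
        ("wm_mask", dataset.wm_mask),
        ("csf_mask", dataset.csf_mask),
    ]:
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), outdir / f"{name}.nii.gz")

    for (subj, sess), series in dataset.bold.items():
        sdir = outdir / subj
        sdir.mkdir(exist_ok=True)
        img = nib.Nifti1Image(series.data.astype(np.float32), affine)
        img.header.set_zooms((voxel_mm,) * 3 + (series.tr_seconds,))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, sdir / f"{subj}_ses{sess}_bold.nii.gz")
        np.savetxt(
            sdir / f"{subj}_ses{sess}_motion.txt",
            dataset.motion[(subj, sess)].as_matrix(),
            fmt="%.8f",
        )

    manifest = dataset.atlas.to_manifest()
    manifest["center"] = [
        ",".join(map(str, roi.center)) for roi in dataset.spec.roi_layout
    ]
    manifest["radius"] = [roi.radius for roi in dataset.spec.roi_layout]
    manifest.to_csv(outdir / "atlas_manifest.tsv", sep="\t", index=False)

    gt = dataset.ground_truth
    payload = {
        "fidelity": gt.fidelity,
        "connectivity": gt.connectivity.tolist(),
        "amplitude_maps": {
            s: {"shape": list(m.shape), "values": m.ravel().tolist()}
            for s, m in gt.amplitude_maps.items()
        },
        "fd_series": {f"{s}_ses{k}": v.tolist() for (s, k), v in gt.fd_series.items()},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload))
    return outdir
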