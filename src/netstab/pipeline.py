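"""End-to-end orchestration: simulate/load -> preprocess -> metrics -> FC -> stability.

One subject-session flows as: drop the first volumes -> build the
Friston-24 motion expansion plus WM/CSF mean regressors -> nuisance
regression -> framewise displacement + scrubbing -> ALFF and fALFF on the
unfiltered residuals; band-pass 0.01-0.1 Hz -> ReHo, degree centrality and
ROI connectivity -> z-score -> smooth. Across the two sessions each
subject then gets a voxel-based Lin CCC per network x metric and a
Spearman stability coefficient per network pair, with Bonferroni /
Benjamini-Hochberg multiplicity handling and group aggregation.

Everything in the report is a pure function of the run configuration and
seed; subjects failing the gross-motion screen are excluded and logged,
mirroring quality-control practice.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .metrics import MetricMap, SmoothingSpec, alff, dc, falff, reho, smooth_map, zscore_map
from .network import FCMatrix, NetworkAtlas, fc_matrix, internetwork_block, roi_mean_series
from .preprocess import (
    BoldSeries,
    MotionTable,
    bandpass,
    build_friston24,
    compute_fd,
    drop_initial_volumes,
    nuisance_regress,
    screen_gross_motion,
    scrub,
)
from .stability import (
    AggregateRow,
    StabilityRecord,
    aggregate,
    bonferroni_alpha,
    fdr_correct,
    label_strength,
    spearman_stability,
    voxel_ccc,
)
from .synthetic import SyntheticDataset, SyntheticSpec, generate_dataset

__all__ = ["RunConfig", "StudyReport", "run_pipeline", "write_report"]

logger = logging.getLogger("netstab")

METRICS = ("ALFF", "fALFF", "ReHo", "DC")
PAIRS = (("DMN", "SN"), ("DMN", "CEN"), ("SN", "CEN"))


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of ``synthetic`` / ``manifest`` set.

    Defaults follow the emulated study: drop 10 volumes, 0.01-0.1 Hz band,
    FD threshold 0.2 mm, DC r-threshold 0.25, 3 mm FWHM smoothing on a
    1.5 mm grid, family-wise alpha 0.05 (Bonferroni over subjects x
    metrics x networks), FDR q 0.01.
    """

    synthetic: SyntheticSpec | None = None
    manifest: str | None = None
    drop_volumes: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.1
    fd_threshold_mm: float = 0.2
    trans_limit_mm: float = 1.5
    rot_limit_deg: float = 1.5
    dc_r_threshold: float = 0.25
    smoothing_fwhm_mm: float = 3.0
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    base_alpha: float = 0.05
    fdr_q: float = 0.01
    ccc_on_smoothed: bool = True
    scrub_spectral_metrics: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.manifest is None):
            raise ValueError("exactly one of synthetic spec or input manifest required")
        for name in ("fd_threshold_mm", "dc_r_threshold", "smoothing_fwhm_mm",
                     "trans_limit_mm", "rot_limit_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        payload = {k: repr(v) for k, v in sorted(self.__dict__.items())}
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]


@dataclass
class SessionResult:
    maps: dict[str, MetricMap]
    fc: FCMatrix
    retained_fraction: float


@dataclass
class StudyReport:
    ccc_records: list[StabilityRecord]
    spearman_records: list[StabilityRecord]
    aggregates_ccc: list[AggregateRow]
    aggregates_spearman: list[AggregateRow]
    excluded_subjects: list[str]
    ccc_alpha: float
    n_ccc_tests: int
    provenance: dict

    def ccc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [r.subject_id for r in self.ccc_records],
                "network": [r.unit for r in self.ccc_records],
                "metric": [r.measure for r in self.ccc_records],
                "ccc": [r.estimate for r in self.ccc_records],
                "label": [r.label for r in self.ccc_records],
            }
        )

    def spearman_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [r.subject_id for r in self.spearman_records],
                "pair": [r.unit for r in self.spearman_records],
                "rho": [r.estimate for r in self.spearman_records],
                "p_adjusted": [r.p_value for r in self.spearman_records],
                "significant": [r.corrected for r in self.spearman_records],
                "label": [r.label for r in self.spearman_records],
            }
        )

    def aggregate_table(self) -> pd.DataFrame:
        rows = self.aggregates_ccc + self.aggregates_spearman
        return pd.DataFrame(
            {
                "unit": [r.unit for r in rows],
                "measure": [r.measure for r in rows],
                "mean": [r.mean for r in rows],
                "sd": [r.sd for r in rows],
                "min": [r.min for r in rows],
                "max": [r.max for r in rows],
                "n_subjects": [r.n_subjects for r in rows],
            }
        )


def _process_session(
    series: BoldSeries,
    motion: MotionTable,
    gm_mask: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    atlas: NetworkAtlas,
    cfg: RunConfig,
) -> SessionResult:
    series = drop_initial_volumes(series, cfg.drop_volumes)
    motion = motion.drop_initial(cfg.drop_volumes)

    wm_mean = series.data[wm_mask].mean(axis=0)
    csf_mean = series.data[csf_mask].mean(axis=0)
    design = np.column_stack([build_friston24(motion), wm_mean, csf_mean])
    series = nuisance_regress(series, design)

    fd = compute_fd(motion)
    fd.threshold_mm = cfg.fd_threshold_mm
    scrubbed, retained = scrub(series, fd)

    spectral_input = scrubbed if cfg.scrub_spectral_metrics else series
    maps = {
        "ALFF": alff(spectral_input, gm_mask, cfg.low_hz, cfg.high_hz),
        "fALFF": falff(spectral_input, gm_mask, cfg.low_hz, cfg.high_hz),
    }

    filtered = bandpass(scrubbed, cfg.low_hz, cfg.high_hz)
    maps["ReHo"] = reho(filtered, gm_mask)
    maps["DC"] = dc(filtered, gm_mask, cfg.dc_r_threshold)

    smoothing = SmoothingSpec(cfg.smoothing_fwhm_mm, cfg.voxel_size_mm)
    finished = {}
    for name, m in maps.items():
        z = zscore_map(m, gm_mask)
        finished[name] = smooth_map(z, smoothing, gm_mask) if cfg.ccc_on_smoothed else z

    fc = fc_matrix(roi_mean_series(filtered, atlas), atlas.names)
    return SessionResult(finished, fc, retained)


def run_pipeline(config: RunConfig, dataset: SyntheticDataset | None = None) -> StudyReport:
    """Run the full two-session stability study described by ``config``.

    ``dataset`` may be passed to reuse an already generated synthetic
    dataset; otherwise it is generated from ``config.synthetic`` (or loaded
    from ``config.manifest``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if dataset is None:
        if config.synthetic is not None:
            dataset = generate_dataset(config.synthetic)
        else:
            dataset = _load_manifest_dataset(config)

    gm, wm, csf = dataset.gm_mask, dataset.wm_mask, dataset.csf_mask
    atlas = dataset.atlas

    included: list[str] = []
    excluded: list[str] = []
    for subj in dataset.subjects:
        bad = False
        for sess in (1, 2):
            motion = dataset.motion[(subj, sess)].drop_initial(config.drop_volumes)
            ok, frames = screen_gross_motion(
                motion, config.trans_limit_mm, config.rot_limit_deg
            )
            if not ok:
                logger.warning(
                    "excluding %s: gross motion in session %d at frames %s",
                    subj, sess, frames[:5],
                )
                bad = True
        (excluded if bad else included).append(subj)
    if not included:
        raise RuntimeError("every subject failed the gross-motion screen")

    n_ccc_tests = len(included) * len(METRICS) * 3  # subjects x metrics x networks
    alpha = bonferroni_alpha(config.base_alpha, n_ccc_tests)

    ccc_records: list[StabilityRecord] = []
    spearman_raw: list[tuple[str, str, float, float]] = []

    for subj in included:
        results = {
            sess: _process_session(
                dataset.bold[(subj, sess)], dataset.motion[(subj, sess)],
                gm, wm, csf, atlas, config,
            )
            for sess in (1, 2)
        }
        for net in ("DMN", "CEN", "SN"):
            net_mask = atlas.network_mask(net)
            for metric in METRICS:
                res = voxel_ccc(
                    results[1].maps[metric], results[2].maps[metric],
                    net_mask, alpha=alpha,
                )
                ccc_records.append(
                    StabilityRecord(
                        subject_id=subj, unit=net, measure=metric,
                        estimate=res.rho_c, corrected=True,
                    )
                )
        for net_a, net_b in PAIRS:
            b1 = internetwork_block(results[1].fc, atlas, net_a, net_b)
            b2 = internetwork_block(results[2].fc, atlas, net_a, net_b)
            rho, p = spearman_stability(b1, b2)
            spearman_raw.append((subj, f"{net_a}/{net_b}", rho, p))

    reject, p_adj = fdr_correct([p for *_, p in spearman_raw], q=config.fdr_q)
    spearman_records = [
        StabilityRecord(
            subject_id=subj, unit=pair, measure=pair,
            estimate=rho, p_value=float(pa), corrected=bool(rej),
            label=label_strength(rho),
        )
        for (subj, pair, rho, _), pa, rej in zip(spearman_raw, p_adj, reject)
    ]

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": _version,
        "n_subjects_included": len(included),
        "excluded": excluded,
        "ccc_alpha": alpha,
        "ci_method": "Lin asymptotic (Fisher-z scale)",
    }
    return StudyReport(
        ccc_records=ccc_records,
        spearman_records=spearman_records,
        aggregates_ccc=aggregate(ccc_records),
        aggregates_spearman=aggregate(spearman_records),
        excluded_subjects=excluded,
        ccc_alpha=alpha,
        n_ccc_tests=n_ccc_tests,
        provenance=provenance,
    )


def _load_manifest_dataset(config: RunConfig) -> SyntheticDataset:
    """Load a study from a manifest directory written by ``write_dataset``.

    The manifest path points at a directory containing the mask NIfTIs,
    ``atlas_manifest.tsv`` and per-subject ``<sub>/<sub>_ses<k>_bold.nii.gz``
    plus motion text files.
    """
    import nibabel as nib

    root = Path(config.manifest)
    if not root.is_dir():
        raise FileNotFoundError(f"manifest directory {root} not found")

    def load_mask(name: str) -> np.ndarray:
        return np.asanyarray(nib.load(root / f"{name}.nii.gz").dataobj).astype(bool)

    brain = load_mask("brain_mask")
    gm = load_mask("gm_mask")
    wm = load_mask("wm_mask")
    csf = load_mask("csf_mask")

    manifest = pd.read_csv(root / "atlas_manifest.tsv", sep="\t")
    rois = []
    for _, row in manifest.iterrows():
        if "nifti_path" in manifest.columns and isinstance(row.get("nifti_path"), str):
            mask = np.asanyarray(nib.load(root / row["nifti_path"]).dataobj).astype(bool)
        else:
            center = tuple(int(v) for v in str(row["center"]).split(","))
            idx = np.indices(brain.shape)
            d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
            mask = d2 <= float(row["radius"]) ** 2
        rois.append((row["roi_name"], row["network"], mask))
    atlas = NetworkAtlas(rois)

    subjects = sorted(p.name for p in root.iterdir() if p.is_dir())
    bold: dict[tuple[str, int], BoldSeries] = {}
    motion: dict[tuple[str, int], MotionTable] = {}
    for subj in subjects:
        for sess in (1, 2):
            img = nib.load(root / subj / f"{subj}_ses{sess}_bold.nii.gz")
            tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 3.0
            bold[(subj, sess)] = BoldSeries(
                np.asanyarray(img.dataobj, dtype=np.float64), tr or 3.0, affine=img.affine
            )
            motion[(subj, sess)] = MotionTable.from_text(
                root / subj / f"{subj}_ses{sess}_motion.txt"
            )
    from .synthetic import GroundTruth

    truth = GroundTruth({}, np.eye(15), float("nan"), {})
    spec = SyntheticSpec(grid_shape=brain.shape, n_subjects=len(subjects))
    return SyntheticDataset(
        spec=spec, subjects=subjects, bold=bold, motion=motion,
        brain_mask=brain, gm_mask=gm, wm_mask=wm, csf_mask=csf,
        atlas=atlas, ground_truth=truth,
    )


def write_report(report: StudyReport, outdir: str | Path) -> Path:
    """Write the report tables (TSV) and provenance (JSON) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.ccc_table().to_csv(outdir / "ccc_per_subject.tsv", sep="\t", index=False)
    report.spearman_table().to_csv(
        outdir / "spearman_per_subject.tsv", sep="\t", index=False
    )
    report.aggregate_table().round(6).to_csv(
        outdir / "aggregates.tsv", sep="\t", index=False
    )
    (outdir / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
    return outdir
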