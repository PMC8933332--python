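"""Triple-network ROI connectivity.

The triple-network model covers three core resting-state networks: the
default mode network (DMN, 4 ROIs), the central executive network (CEN,
4 ROIs) and the salience network (SN, 7 ROIs) — 15 ROIs in total. This
module extracts each ROI's mean band-passed BOLD series, builds the 15x15
Pearson correlation matrix per session (with its Fisher r-to-z transform),
and vectorizes the internetwork cross-blocks whose inter-session agreement
the stability analysis quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import BoldSeries

__all__ = [
    "NETWORKS",
    "NETWORK_SIZES",
    "DEFAULT_ROI_NAMES",
    "NetworkAtlas",
    "FCMatrix",
    "roi_mean_series",
    "fc_matrix",
    "internetwork_block",
]

NETWORKS = ("DMN", "CEN", "SN")
NETWORK_SIZES = {"DMN": 4, "CEN": 4, "SN": 7}

# ROI naming follows the Conn-toolbox network atlas labels
DEFAULT_ROI_NAMES = {
    "DMN": ["MPFC", "LP(L)", "LP(R)", "PCC"],
    "CEN": ["lPFC", "rPFC", "PPC(L)", "PPC(R)"],
    "SN": ["ACC", "Insula(L)", "Insula(R)", "RPFC(L)", "RPFC(R)", "SMG(L)", "SMG(R)"],
}

_Z_CLIP = 1.0 - 1e-12


@dataclass
class NetworkAtlas:
    """Fifteen named ROI masks with their network assignments.

    ``rois`` is an ordered list of ``(name, network, mask)`` with 3D binary
    masks on the acquisition grid. Network sizes are fixed at DMN=4, CEN=4,
    SN=7 and the masks must be nonempty.
    """

    rois: list[tuple[str, str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rois) != 15:
            raise ValueError(f"atlas must contain exactly 15 ROIs, got {len(self.rois)}")
        counts = {net: 0 for net in NETWORKS}
        for name, net, mask in self.rois:
            if net not in NETWORKS:
                raise ValueError(f"ROI {name!r} has unknown network {net!r}")
            counts[net] += 1
            if not np.asarray(mask).astype(bool).any():
                raise ValueError(f"ROI {name!r} has an empty mask")
        if counts != NETWORK_SIZES:
            raise ValueError(f"network sizes {counts} != required {NETWORK_SIZES}")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.rois]

    @property
    def networks(self) -> list[str]:
        return [net for _, net, _ in self.rois]

    def network_indices(self, network: str) -> np.ndarray:
        """Row indices of a network's ROIs in atlas order."""
        if network not in NETWORKS:
            raise ValueError(f"unknown network {network!r}")
        return np.array([i for i, (_, net, _) in enumerate(self.rois) if net == network])

    def network_mask(self, network: str) -> np.ndarray:
        """Union of a network's ROI masks."""
        idx = self.network_indices(network)
        out = np.zeros_like(np.asarray(self.rois[0][2]), dtype=bool)
        for i in idx:
            out |= np.asarray(self.rois[i][2]).astype(bool)
        return out

    def to_manifest(self) -> pd.DataFrame:
        """Tabular view (roi_name, network) in atlas order."""
        return pd.DataFrame({"roi_name": self.names, "network": self.networks})


@dataclass
class FCMatrix:
    """A 15x15 ROI correlation matrix in r and Fisher-z forms."""

    r: np.ndarray
    z: np.ndarray
    roi_order: list[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.r.shape != (len(self.roi_order),) * 2:
            raise ValueError("matrix shape does not match ROI order")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")


def roi_mean_series(series: BoldSeries, atlas: NetworkAtlas) -> np.ndarray:
    """Unweighted ROI-mean time series over kept frames, shape (15, n_kept)."""
    data = series.kept_data()
    out = np.empty((len(atlas.rois), data.shape[-1]))
    for i, (name, _, mask) in enumerate(atlas.rois):
        m = np.asarray(mask).astype(bool)
        if m.shape != series.data.shape[:3]:
            raise ValueError(f"ROI {name!r} mask shape mismatch")
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty")
        out[i] = data[m].mean(axis=0)
    return out


def fc_matrix(roi_series: np.ndarray, roi_order: list[str] | None = None) -> FCMatrix:
    """Pairwise Pearson correlations between ROI mean series, plus Fisher z.

    z = atanh(r) off-diagonal, with |r| clipped to 1 - 1e-12 so degenerate
    perfectly correlated pairs stay finite; the diagonal of z is NaN.
    """
    roi_series = np.asarray(roi_series, dtype=np.float64)
    n_roi, n_t = roi_series.shape
    if n_t < 10:
        raise ValueError("need at least 10 time points")
    sds = roi_series.std(axis=1)
    if np.any(sds == 0):
        bad = int(np.argmax(sds == 0))
        raise ValueError(f"ROI series {bad} has zero variance")
    if roi_order is None:
        roi_order = [f"ROI{i:02d}" for i in range(n_roi)]

    r = np.corrcoef(roi_series)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    np.fill_diagonal(z, np.nan)
    return FCMatrix(r, z, list(roi_order))


def internetwork_block(
    fc: FCMatrix, atlas: NetworkAtlas, net_a: str, net_b: str
) -> np.ndarray:
    """Vectorized Fisher-z cross-block between two distinct networks.

    Row-major in atlas order: DMN x CEN gives 16 values, DMN x SN and
    CEN x SN give 28 each.
    """
    if net_a == net_b:
        raise ValueError("networks must differ")
    ia = atlas.network_indices(net_a)
    ib = atlas.network_indices(net_b)
    return fc.z[np.ix_(ia, ib)].ravel()
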