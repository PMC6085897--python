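"""Region-pair functional connectivity: MeanTS and ALPACA edge weights.

Two complementary edge definitions over the same parcellation:

* **MeanTS** — the Pearson correlation of the two regions' voxel-averaged
  time series; sensitive to connectivity that is homogeneous over the pair.
* **ALPACA** (Anatomic and Local Peak Activity Correlation Analysis) — the
  maximum Pearson correlation over all voxel pairs spanning the two regions,
  together with the location of that peak pair; sensitive to focal
  connectivity confined to small subregions.

Edge weights are Fisher r-to-z transformed before any parametric statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .preprocess import LabeledVolume

logger = logging.getLogger(__name__)

METHODS = ("meants", "alpaca")


class DegenerateEdgeError(ValueError):
    """An edge whose correlation is undefined (zero-variance series)."""


class ConnectomeError(ValueError):
    pass


def meants_edge(voxels_a: np.ndarray, voxels_b: np.ndarray) -> float:
    """Pearson correlation of the two regions' mean time series.

    ``voxels_a``/``voxels_b`` are (n_voxels, t) arrays. Zero-variance voxels
    still participate in the average (they shift the mean but carry no
    signal); a zero-variance *mean* series makes the edge degenerate.
    """
    a = np.asarray(voxels_a, dtype=float)
    b = np.asarray(voxels_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateEdgeError("empty voxel set")
    if a.shape[1] != b.shape[1]:
        raise ConnectomeError("time series lengths differ")
    if a.shape[1] < 3:
        raise ConnectomeError("need at least 3 time points")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    sa, sb = ma.std(), mb.std()
    if sa == 0 or sb == 0:
        raise DegenerateEdgeError("zero-variance mean time series")
    r = float(np.corrcoef(ma, mb)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize; returns (z, keep-mask of nonzero-variance rows)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    z = np.zeros_like(x, dtype=float)
    z[keep] = (x[keep] - mu[keep]) / sd[keep]
    return z, keep


def alpaca_edge(
    voxels_a: np.ndarray, voxels_b: np.ndarray
) -> tuple[float, tuple[int, int]]:
    """Peak voxel-pair Pearson correlation and its (i, j) argmax.

    All cross-region voxel-pair correlations are computed as one matrix
    product of standardized series; zero-variance voxels are dropped from
    the candidate set. Ties resolve to the smallest (i, j) in scan order
    (row-major argmax). Indices refer to rows of the *input* arrays.
    """
    a = np.asarray(voxels_a, dtype=float)
    b = np.asarray(voxels_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateEdgeError("empty voxel set")
    if a.shape[1] != b.shape[1]:
        raise ConnectomeError("time series lengths differ")
    t = a.shape[1]
    if t < 3:
        raise ConnectomeError("need at least 3 time points")
    za, keep_a = _standardize(a)
    zb, keep_b = _standardize(b)
    ia = np.flatnonzero(keep_a)
    ib = np.flatnonzero(keep_b)
    if ia.size == 0 or ib.size == 0:
        raise DegenerateEdgeError("all candidate voxel pairs degenerate")
    corr = (za[ia] @ zb[ib].T) / t
    flat = int(np.argmax(corr))
    i, j = divmod(flat, ib.size)
    r = float(np.clip(corr[i, j], -1.0, 1.0))
    return r, (int(ia[i]), int(ib[j]))


def alpaca_edge_bruteforce(
    voxels_a: np.ndarray, voxels_b: np.ndarray
) -> tuple[float, tuple[int, int]]:
    """Exhaustive double-loop reference for the peak voxel-pair correlation.

    Independent of the vectorized path; used as an oracle in tests.
    """
    a = np.asarray(voxels_a, dtype=float)
    b = np.asarray(voxels_b, dtype=float)
    best_r, best_pair = -np.inf, None
    for i in range(a.shape[0]):
        if a[i].std() == 0:
            continue
        for j in range(b.shape[0]):
            if b[j].std() == 0:
                continue
            r = float(np.corrcoef(a[i], b[j])[0, 1])
            if r > best_r:
                best_r, best_pair = r, (i, j)
    if best_pair is None:
        raise DegenerateEdgeError("all candidate voxel pairs degenerate")
    return best_r, best_pair


def fisher_z(r: float, clip_epsilon: float = 1e-5) -> float:
    """Fisher r-to-z transform with clamping away from |r| = 1."""
    if abs(r) > 1 + 1e-12:
        raise ConnectomeError(f"correlation {r} outside [-1, 1]")
    return float(np.arctanh(np.clip(r, -1 + clip_epsilon, 1 - clip_epsilon)))


@dataclass
class Connectome:
    """Symmetric region-by-region Fisher-z connectivity matrix."""

    method: str
    regions: list[str]                   # region keys, fixed order
    z: np.ndarray                        # (n, n), NaN diagonal
    peak_voxels: dict[tuple[str, str], tuple[tuple[int, ...], tuple[int, ...]]] = field(
        default_factory=dict
    )
    missing_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConnectomeError(f"unknown method {self.method!r}")
        n = len(self.regions)
        if n < 2:
            raise ConnectomeError("need at least 2 regions")
        if self.z.shape != (n, n):
            raise ConnectomeError("z matrix shape does not match region list")

    def edge(self, key_a: str, key_b: str) -> float:
        i, j = self.regions.index(key_a), self.regions.index(key_b)
        return float(self.z[i, j])

    def edge_series(self) -> pd.Series:
        """Upper-triangle edges as a Series indexed by (region_a, region_b)."""
        n = len(self.regions)
        idx, vals = [], []
        for i in range(n):
            for j in range(i + 1, n):
                idx.append((self.regions[i], self.regions[j]))
                vals.append(self.z[i, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx))

    # -- I/O --------------------------------------------------------------
    def to_edge_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.regions)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = self.regions[i], self.regions[j]
                row = {"region_a": a, "region_b": b, "z": self.z[i, j]}
                if self.method == "alpaca" and (a, b) in self.peak_voxels:
                    pa, pb = self.peak_voxels[(a, b)]
                    row["peak_a_ijk"] = ",".join(map(str, pa))
                    row["peak_b_ijk"] = ",".join(map(str, pb))
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_edge_frame().to_csv(path, sep="\t", index=False)
        meta = {
            "method": self.method,
            "regions": self.regions,
            "missing_edges": [list(e) for e in self.missing_edges],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: Path) -> "Connectome":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        regions = meta["regions"]
        n = len(regions)
        z = np.full((n, n), np.nan)
        peaks: dict = {}
        df = pd.read_csv(path, sep="\t")
        pos = {k: i for i, k in enumerate(regions)}
        for _, row in df.iterrows():
            i, j = pos[row["region_a"]], pos[row["region_b"]]
            z[i, j] = z[j, i] = row["z"]
            if "peak_a_ijk" in df.columns and isinstance(row.get("peak_a_ijk"), str):
                peaks[(row["region_a"], row["region_b"])] = (
                    tuple(int(v) for v in row["peak_a_ijk"].split(",")),
                    tuple(int(v) for v in row["peak_b_ijk"].split(",")),
                )
        return cls(
            method=meta["method"],
            regions=regions,
            z=z,
            peak_voxels=peaks,
            missing_edges=[tuple(e) for e in meta.get("missing_edges", [])],
        )


def region_voxel_series(
    v: LabeledVolume, atlas: RegionAtlas, keys: list[str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-region (series, coordinates) over ROI ∩ brain-mask voxels.

    ``series`` is (n_voxels, t); ``coordinates`` is the matching (n_voxels, 3)
    voxel index array, in scan order.
    """
    out = {}
    for key in keys:
        roi = (v.labels == atlas.region(key).label) & v.brain_mask
        coords = np.argwhere(roi)
        out[key] = (v.data[roi], coords)
    return out


def build_connectome(
    v: LabeledVolume,
    atlas: RegionAtlas,
    included_regions: list[str],
    method: str,
    clip_epsilon: float = 1e-5,
) -> Connectome:
    """Assemble the full symmetric Fisher-z connectome for one subject.

    Only voxels inside both the ROI and the subject's brain mask contribute.
    Degenerate edges are recorded as missing (NaN) with a logged list rather
    than silently zeroed.
    """
    if method not in METHODS:
        raise ConnectomeError(f"unknown method {method!r}")
    if len(included_regions) < 2:
        raise ConnectomeError("need at least 2 included regions")
    series = region_voxel_series(v, atlas, included_regions)
    n = len(included_regions)
    z = np.full((n, n), np.nan)
    peaks: dict = {}
    missing: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = included_regions[i], included_regions[j]
            sa, ca = series[a]
            sb, cb = series[b]
            try:
                if method == "meants":
                    r = meants_edge(sa, sb)
                else:
                    r, (pi, pj) = alpaca_edge(sa, sb)
                    peaks[(a, b)] = (tuple(ca[pi]), tuple(cb[pj]))
            except DegenerateEdgeError:
                missing.append((a, b))
                continue
            z[i, j] = z[j, i] = fisher_z(r, clip_epsilon)
    if missing:
        logger.warning("degenerate edges recorded as missing: %s", missing)
    return Connectome(
        method=method,
        regions=list(included_regions),
        z=z,
        peak_voxels=peaks,
        missing_edges=missing,
    )
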