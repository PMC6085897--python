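"""Region atlas for native-space connectome analysis.

The region vocabulary follows the FreeSurfer-style parcellation commonly used
in pediatric connectome studies: 34 cortical and 7 subcortical regions per
hemisphere, minus six cortical regions routinely dropped for susceptibility
artifacts, leaving 35 regions per hemisphere grouped into five anatomical
clusters (frontal, occipital, parietal, subcortical, temporal).

Phantom atlases place each region as a rectangular voxel block in the left
half of the grid and mirror it across the mid-sagittal plane, which gives
exact left/right symmetry — convenient for testing hemispheric-symmetry
classification downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

GROUPS = ("Fro", "Occ", "Par", "Sub", "Temp")

# (name, abbreviation, group); order within group is the conventional listing.
REGION_VOCABULARY: tuple[tuple[str, str, str], ...] = (
    ("Caudal anterior cingulate cortex", "Cac", "Fro"),
    ("Caudal middle frontal gyrus", "Cmf", "Fro"),
    ("Isthmus of cingulate gyrus", "ICG", "Fro"),
    ("Paracentral lobule", "PCe", "Fro"),
    ("Pars opercularis", "POp", "Fro"),
    ("Pars orbitalis", "POb", "Fro"),
    ("Pars triangularis", "PTr", "Fro"),
    ("Posterior cingulate gyrus", "PCi", "Fro"),
    ("Precentral gyrus", "PrC", "Fro"),
    ("Rostral anterior cingulate gyrus", "RAC", "Fro"),
    ("Rostral middle frontal gyrus", "RMF", "Fro"),
    ("Superior frontal gyrus", "SFr", "Fro"),
    ("Cuneus", "Cun", "Occ"),
    ("Lateral occipital gyrus", "LOc", "Occ"),
    ("Lingual gyrus", "Lin", "Occ"),
    ("Pericalcarine cortex", "Pcc", "Occ"),
    ("Inferior parietal lobule", "IPa", "Par"),
    ("Postcentral gyrus", "PoC", "Par"),
    ("Precuneus", "Pcn", "Par"),
    ("Superior parietal lobule", "SPa", "Par"),
    ("Supramarginal gyrus", "SMa", "Par"),
    ("Accumbens area", "Acc", "Sub"),
    ("Amygdala", "Amg", "Sub"),
    ("Caudate", "CaN", "Sub"),
    ("Hippocampus", "Hip", "Sub"),
    ("Pallidum", "Pal", "Sub"),
    ("Putamen", "Put", "Sub"),
    ("Thalamus", "Tha", "Sub"),
    ("Banks of superior temporal sulcus", "BSt", "Temp"),
    ("Fusiform gyrus", "Fus", "Temp"),
    ("Insula", "Ins", "Temp"),
    ("Middle temporal gyrus", "MTe", "Temp"),
    ("Parahippocampal gyrus", "Phc", "Temp"),
    ("Superior temporal gyrus", "STe", "Temp"),
    ("Transverse temporal gyrus", "TrT", "Temp"),
)

#: Cortical regions conventionally excluded for susceptibility artifacts
#: (low brain-mask overlap near air/tissue interfaces). Not part of the
#: default vocabulary; phantoms may include them to exercise the manual
#: exclusion rule.
SUSCEPTIBILITY_EXCLUDED_REGIONS: tuple[tuple[str, str, str], ...] = (
    ("Entorhinal cortex", "Ent", "Temp"),
    ("Frontal pole", "FPo", "Fro"),
    ("Inferior temporal gyrus", "ITe", "Temp"),
    ("Lateral orbitofrontal cortex", "LOF", "Fro"),
    ("Medial orbitofrontal cortex", "MOF", "Fro"),
    ("Temporal pole", "TPo", "Temp"),
)

SUSCEPTIBILITY_EXCLUDED_NAMES: tuple[str, ...] = tuple(
    n for n, _, _ in SUSCEPTIBILITY_EXCLUDED_REGIONS
)


class AtlasError(ValueError):
    """Raised for invalid atlas construction requests."""


@dataclass(frozen=True)
class Region:
    label: int
    name: str
    abbreviation: str
    hemisphere: str  # "L" or "R"
    group: str       # one of GROUPS

    @property
    def key(self) -> str:
        """Hemisphere-qualified identifier, e.g. ``Tha_L``."""
        return f"{self.abbreviation}_{self.hemisphere}"


@dataclass
class RegionAtlas:
    """A parcellation: region metadata plus an integer label volume."""

    regions: list[Region]
    label_volume: np.ndarray  # 3D int, 0 = background
    _by_label: dict[int, Region] = field(init=False, repr=False)
    _by_key: dict[str, Region] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_label = {r.label: r for r in self.regions}
        self._by_key = {r.key: r for r in self.regions}
        self.validate()

    def validate(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise AtlasError("duplicate region label codes")
        if any(l <= 0 for l in labels):
            raise AtlasError("label codes must be positive")
        pairs = [(r.name, r.hemisphere) for r in self.regions]
        if len(set(pairs)) != len(pairs):
            raise AtlasError("duplicate (name, hemisphere) region pair")
        bad = {r.group for r in self.regions} - set(GROUPS)
        if bad:
            raise AtlasError(f"unknown anatomical groups: {sorted(bad)}")
        present = set(np.unique(self.label_volume)) - {0}
        missing = set(labels) - present
        if missing:
            raise AtlasError(f"regions without voxels: {sorted(missing)}")

    # -- lookup -----------------------------------------------------------
    def region(self, key_or_label: str | int) -> Region:
        if isinstance(key_or_label, (int, np.integer)):
            return self._by_label[int(key_or_label)]
        return self._by_key[key_or_label]

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    @property
    def keys(self) -> list[str]:
        return [r.key for r in self.regions]

    def voxel_indices(self, key: str) -> np.ndarray:
        """(n_voxels, 3) integer coordinates of a region, scan order."""
        return np.argwhere(self.label_volume == self.region(key).label)

    def voxel_count(self, key: str) -> int:
        return int((self.label_volume == self.region(key).label).sum())

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                str(r.label): {
                    "name": r.name,
                    "abbreviation": r.abbreviation,
                    "hemisphere": r.hemisphere,
                    "group": r.group,
                }
                for r in self.regions
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str, label_volume: np.ndarray) -> "RegionAtlas":
        meta = json.loads(text)
        regions = [
            Region(int(lbl), m["name"], m["abbreviation"], m["hemisphere"], m["group"])
            for lbl, m in meta.items()
        ]
        return cls(regions, label_volume)


def _vocabulary(include_excluded: bool) -> list[tuple[str, str, str]]:
    vocab = list(REGION_VOCABULARY)
    if include_excluded:
        vocab += list(SUSCEPTIBILITY_EXCLUDED_REGIONS)
    return vocab


def build_phantom_atlas(
    grid_shape: Sequence[int],
    regions_per_group: Mapping[str, int] | str = "full",
    block_shape: Sequence[int] = (4, 4, 4),
    include_excluded: bool = False,
) -> RegionAtlas:
    """Build a mirrored block phantom atlas.

    Parameters
    ----------
    grid_shape
        Voxel grid (nx, ny, nz); the first axis is left-right and must be
        even so the mid-sagittal mirror is exact.
    regions_per_group
        Either ``"full"`` (the whole 35-region vocabulary per hemisphere) or
        a mapping group -> number of regions to draw from that group, in
        vocabulary order.
    block_shape
        Shape of each region's rectangular voxel block.
    include_excluded
        Also place the six susceptibility-artifact cortical regions
        (useful for testing the manual-exclusion rule).

    Each left-hemisphere region occupies a block in the ``x < nx/2`` half;
    its right twin is the mirror image under ``x -> nx - 1 - x``, so paired
    regions have identical voxel counts.
    """
    nx, ny, nz = (int(v) for v in grid_shape)
    if nx % 2:
        raise AtlasError("first grid axis must be even for mid-sagittal mirroring")
    vocab = _vocabulary(include_excluded)
    if regions_per_group == "full":
        chosen = vocab
    else:
        chosen = []
        for group, count in regions_per_group.items():
            if group not in GROUPS:
                raise AtlasError(f"unknown group {group!r}")
            pool = [v for v in vocab if v[2] == group]
            if count > len(pool):
                raise AtlasError(
                    f"group {group!r} has only {len(pool)} regions, {count} requested"
                )
            chosen.extend(pool[:count])

    bx, by, bz = (int(v) for v in block_shape)
    # one-voxel gap between blocks guarantees background voxels
    sx, sy, sz = bx + 1, by + 1, bz + 1
    half = nx // 2
    slots = [
        (ox, oy, oz)
        for ox in range(0, half - bx + 1, sx)
        for oy in range(0, ny - by + 1, sy)
        for oz in range(0, nz - bz + 1, sz)
    ]
    if len(slots) < len(chosen):
        raise AtlasError(
            f"grid {grid_shape} holds {len(slots)} blocks of {tuple(block_shape)} "
            f"per hemisphere but {len(chosen)} regions were requested "
            f"(short by {len(chosen) - len(slots)})"
        )

    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    regions: list[Region] = []
    n = len(chosen)
    for i, ((name, abbr, group), (ox, oy, oz)) in enumerate(zip(chosen, slots)):
        lab_l, lab_r = i + 1, n + i + 1
        labels[ox : ox + bx, oy : oy + by, oz : oz + bz] = lab_l
        labels[nx - ox - bx : nx - ox, oy : oy + by, oz : oz + bz] = lab_r
        regions.append(Region(lab_l, name, abbr, "L", group))
        regions.append(Region(lab_r, name, abbr, "R", group))
    return RegionAtlas(regions, labels)
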