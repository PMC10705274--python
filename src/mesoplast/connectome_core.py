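"""Domain types, atlas handling, connectome normalization, and matrix I/O.

The package works on the 90-region AAL parcellation (45 regions per
hemisphere).  Structural connectomes (SC) are symmetric nonnegative weight
matrices, max-normalized so the strongest connection equals 1; functional
connectomes (FC) are Pearson-correlation matrices with unit diagonal.
Everything downstream (model integration, fitting, graph analysis) consumes
the containers defined here.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from importlib import resources
from typing import Iterable

import numpy as np

__all__ = [
    "MesoplastError",
    "MalformedAtlasError",
    "UnpairedRegionError",
    "MatrixParseError",
    "AsymmetryError",
    "RegionRecord",
    "AtlasTable",
    "StructuralConnectome",
    "FunctionalConnectome",
    "Subject",
    "GroupDataset",
    "KNOWN_LOBE_TAGS",
    "load_atlas",
    "default_atlas",
    "normalize_sc",
    "select_mask",
    "read_matrix",
    "write_matrix",
]

#: Lobe tags recognized by :func:`select_mask`.  The parieto-occipital
#: subnetwork used throughout the analyses is the union of ``parietal`` and
#: ``occipital``.
KNOWN_LOBE_TAGS = frozenset(
    {"frontal", "parietal", "occipital", "temporal", "limbic", "subcortical", "central"}
)

SYMMETRY_TOL = 1e-9


class MesoplastError(Exception):
    """Base class for all package errors."""


class MalformedAtlasError(MesoplastError):
    """Atlas table violates a structural constraint (duplicates, bad tags)."""


class UnpairedRegionError(MalformedAtlasError):
    """A region has no homotopic partner in the opposite hemisphere."""


class MatrixParseError(MesoplastError):
    """Delimited-text matrix could not be parsed as a square numeric array."""


class AsymmetryError(MesoplastError):
    """Matrix expected to be symmetric is not, beyond tolerance."""


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionRecord:
    """One parcellation region.

    Attributes
    ----------
    index : 0-based position in matrix order.
    name : full anatomical name.
    abbreviation : short code, e.g. ``"SOG"``.
    hemisphere : ``"L"`` or ``"R"``.
    lobe_tags : subset of :data:`KNOWN_LOBE_TAGS`.
    homotopic_partner : index of the same region in the other hemisphere.
    """

    index: int
    name: str
    abbreviation: str
    hemisphere: str
    lobe_tags: frozenset[str]
    homotopic_partner: int

    @property
    def label(self) -> str:
        return f"{self.abbreviation}.{self.hemisphere}"


@dataclass(frozen=True)
class AtlasTable:
    """Ordered region table with homotopic pairing resolved."""

    regions: tuple[RegionRecord, ...]

    @property
    def n(self) -> int:
        return len(self.regions)

    def __post_init__(self) -> None:
        for i, r in enumerate(self.regions):
            if r.index != i:
                raise MalformedAtlasError(f"region indices must be 0..n-1; got {r.index} at {i}")
            p = self.regions[r.homotopic_partner]
            if p.homotopic_partner != r.index or p.hemisphere == r.hemisphere:
                raise UnpairedRegionError(f"homotopic pairing broken at region {r.label}")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise MalformedAtlasError("abbreviation+hemisphere labels are not unique")

    def partner(self, index: int) -> int:
        return self.regions[index].homotopic_partner

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """All (left, right) homotopic index pairs, ordered by left index."""
        pairs = []
        for r in self.regions:
            if r.index < r.homotopic_partner:
                pairs.append((r.index, r.homotopic_partner))
        return pairs

    def by_label(self, label: str) -> RegionRecord:
        """Look up a region by ``ABBR.H`` label (e.g. ``"SOG.L"``)."""
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)


def load_atlas(path: str | Path | None = None) -> AtlasTable:
    """Load a region table from CSV (bundled AAL90 table when *path* is None).

    The CSV has columns ``index,name,abbreviation,hemisphere,lobe_tags,
    partner_abbreviation`` with lobe tags semicolon-separated.  Homotopic
    partners are resolved by matching abbreviation across hemispheres, never
    by index arithmetic.
    """
    if path is None:
        text = (resources.files("mesoplast") / "data" / "aal90.csv").read_text()
    else:
        text = Path(path).read_text()
    reader = csv.DictReader(io.StringIO(text))
    raw: list[dict] = list(reader)
    if not raw:
        raise MalformedAtlasError("empty atlas table")

    seen: set[tuple[str, str]] = set()
    for row in raw:
        key = (row["abbreviation"], row["hemisphere"])
        if key in seen:
            raise MalformedAtlasError(f"duplicate abbreviation within hemisphere: {key}")
        seen.add(key)

    # abbreviation -> hemisphere -> row position
    index_of: dict[tuple[str, str], int] = {
        (row["abbreviation"], row["hemisphere"]): i for i, row in enumerate(raw)
    }
    regions = []
    for i, row in enumerate(raw):
        hemi = row["hemisphere"]
        if hemi not in ("L", "R"):
            raise MalformedAtlasError(f"hemisphere must be L or R, got {hemi!r}")
        tags = frozenset(t for t in row["lobe_tags"].split(";") if t)
        unknown = tags - KNOWN_LOBE_TAGS
        if unknown:
            raise MalformedAtlasError(f"unknown lobe tags {sorted(unknown)} in region {row['abbreviation']}")
        other = "R" if hemi == "L" else "L"
        partner_key = (row.get("partner_abbreviation") or row["abbreviation"], other)
        if partner_key not in index_of:
            raise UnpairedRegionError(
                f"region {row['abbreviation']}.{hemi} has no partner {partner_key[0]}.{other}"
            )
        regions.append(
            RegionRecord(
                index=i,
                name=row["name"],
                abbreviation=row["abbreviation"],
                hemisphere=hemi,
                lobe_tags=tags,
                homotopic_partner=index_of[partner_key],
            )
        )
    return AtlasTable(regions=tuple(regions))


_DEFAULT_ATLAS: AtlasTable | None = None


def default_atlas() -> AtlasTable:
    """The bundled 90-region AAL table (cached)."""
    global _DEFAULT_ATLAS
    if _DEFAULT_ATLAS is None:
        _DEFAULT_ATLAS = load_atlas(None)
    return _DEFAULT_ATLAS


def select_mask(atlas: AtlasTable, tags: Iterable[str]) -> set[int]:
    """Indices of regions whose lobe tags intersect *tags*.

    ``select_mask(atlas, {"parietal", "occipital"})`` yields the
    parieto-occipital subnetwork mask.
    """
    tagset = set(tags)
    if not tagset:
        raise ValueError("tag set must be nonempty")
    unknown = tagset - KNOWN_LOBE_TAGS
    if unknown:
        raise ValueError(f"unknown lobe tags: {sorted(unknown)}")
    return {r.index for r in atlas.regions if r.lobe_tags & tagset}


# ---------------------------------------------------------------------------
# Connectome containers
# ---------------------------------------------------------------------------

VALID_GROUPS = ("VGP", "NVGP", "CVGP", "synthetic")


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative weight matrix (the coupling matrix M)."""

    weights: np.ndarray
    subject_id: str = "unknown"
    group: str = "synthetic"

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"SC must be square, got shape {w.shape}")
        self.weights = w


@dataclass
class FunctionalConnectome:
    """Symmetric correlation matrix with unit diagonal."""

    values: np.ndarray
    source: str = "simulated"  # simulated | target | empirical

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"FC must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=SYMMETRY_TOL):
            raise AsymmetryError("FC matrix is not symmetric")
        self.values = v


@dataclass
class Subject:
    sc: StructuralConnectome
    playing_time: float  # hours per week, >= 0

    def __post_init__(self) -> None:
        if self.playing_time < 0:
            raise ValueError("playing_time must be >= 0")


@dataclass
class GroupDataset:
    """A cohort: subjects with SC and playing time, plus the fitting target FC."""

    subjects: list[Subject]
    target_fc: FunctionalConnectome
    atlas: AtlasTable

    def __post_init__(self) -> None:
        n = self.atlas.n
        for s in self.subjects:
            if s.sc.n != n:
                raise ValueError(
                    f"subject {s.sc.subject_id} SC dimension {s.sc.n} != atlas n {n}"
                )
        if self.target_fc.n != n:
            raise ValueError("target FC dimension does not match atlas")

    def group(self, label: str) -> list[Subject]:
        return [s for s in self.subjects if s.sc.group == label]

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.subjects:
            if s.sc.group not in seen:
                seen.append(s.sc.group)
        return seen


# ---------------------------------------------------------------------------
# Normalization and I/O
# ---------------------------------------------------------------------------

def normalize_sc(
    raw: np.ndarray, subject_id: str = "unknown", group: str = "synthetic"
) -> StructuralConnectome:
    """Max-normalize a raw weight matrix into a :class:`StructuralConnectome`.

    Every entry is divided by the global maximum; the diagonal is forced to
    zero.  An all-zero matrix is returned unchanged.

    Raises
    ------
    AsymmetryError : asymmetric beyond 1e-9.
    ValueError : negative entries.
    """
    w = np.asarray(raw, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"SC must be square, got shape {w.shape}")
    if not np.allclose(w, w.T, atol=SYMMETRY_TOL):
        raise AsymmetryError("SC matrix asymmetric beyond 1e-9")
    if (w < 0).any():
        raise ValueError("SC weights must be nonnegative")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    m = w.max()
    if m > 0:
        w = w / m
    return StructuralConnectome(weights=w, subject_id=subject_id, group=group)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a square matrix from delimited text (comma or whitespace)."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    delim = "," if "," in lines[0] else None
    rows = []
    width = None
    for k, ln in enumerate(lines):
        toks = [t for t in (ln.split(delim) if delim else ln.split())]
        toks = [t.strip() for t in toks if t.strip()]
        try:
            row = [float(t) for t in toks]
        except ValueError as exc:
            raise MatrixParseError(f"{path}: non-numeric token on line {k + 1}") from exc
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise MatrixParseError(f"{path}: ragged row at line {k + 1}")
        rows.append(row)
    mat = np.asarray(rows, dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise MatrixParseError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
    return mat


def write_matrix(matrix: np.ndarray, path: str | Path, delimiter: str = ",") -> None:
    """Write a full square matrix as delimited text, round-trip safe to 1e-12."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("only square matrices are written")
    np.savetxt(path, mat, fmt="%.17g", delimiter=delimiter)
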