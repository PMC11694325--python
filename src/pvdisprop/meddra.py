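"""Toy MedDRA-style term hierarchy and tumor-event classification.

MedDRA proper is licensed and cannot be redistributed, so the package ships a
small synthetic PT -> HLT -> HLGT -> SOC hierarchy (``data/meddra_toy.tsv``)
covering the tumor preferred terms the study workflow targets plus a spread of
common non-tumor reactions across System Organ Classes.  Every PT carries
exactly one primary path (no multiaxiality) and tumor PTs additionally carry
an anatomical site used for tumor-site profiles.

A case is a tumor adverse event (TAE) iff its reaction set intersects the
hierarchy's tumor PT set.  Term matching is case-insensitive exact string
match after whitespace normalization; there is no fuzzy matching, so
classification is deterministic.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The ten tumor PTs the disproportionality scan singles out, plus the three
#: additional tumor terms named in the descriptive analysis.
DEFAULT_TUMOR_PTS: tuple[str, ...] = (
    "Gastric cancer",
    "Gastric adenocarcinoma",
    "Renal cell carcinoma",
    "Metastatic gastric cancer",
    "Gastric neoplasm",
    "Adenocarcinoma",
    "Renal neoplasm",
    "Gastric cancer stage III",
    "Precancerous cells present",
    "Oesophageal cancer metastatic",
    "Malignant neoplasm",
    "Renal cancer",
    "Breast cancer",
)

UNSPECIFIED_SITE = "unspecified"


class HierarchyError(ValueError):
    """Raised when a hierarchy file violates the single-primary-path rules."""


def normalize_term(term: str) -> str:
    """Whitespace-normalize and lowercase a term for matching."""
    return " ".join(str(term).split()).lower()


@dataclass(frozen=True)
class MedDRAHierarchy:
    """Mapping from PT through HLT and HLGT to SOC, plus the tumor-term set.

    Attributes
    ----------
    paths:
        normalized PT -> (HLT, HLGT, SOC) display labels.
    tumor_pts:
        normalized PT labels designated tumor adverse events (subset of paths).
    sites:
        normalized tumor PT -> anatomical site label.
    labels:
        normalized PT -> display label as read from the fixture.
    """

    paths: Mapping[str, tuple[str, str, str]]
    tumor_pts: frozenset[str]
    sites: Mapping[str, str] = field(default_factory=dict)
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        stray = self.tumor_pts - set(self.paths)
        if stray:
            raise HierarchyError(f"tumor PTs missing from hierarchy: {sorted(stray)}")

    def __len__(self) -> int:
        return len(self.paths)

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self.paths

    def display(self, pt: str) -> str:
        return self.labels.get(normalize_term(pt), pt)

    def soc(self, pt: str) -> str | None:
        path = self.paths.get(normalize_term(pt))
        return path[2] if path else None

    def hlt(self, pt: str) -> str | None:
        path = self.paths.get(normalize_term(pt))
        return path[0] if path else None

    def hlgt(self, pt: str) -> str | None:
        path = self.paths.get(normalize_term(pt))
        return path[1] if path else None

    def is_tumor(self, pt: str) -> bool:
        return normalize_term(pt) in self.tumor_pts

    def site(self, pt: str) -> str | None:
        """Anatomical site of a tumor PT (``None`` for non-tumor terms)."""
        key = normalize_term(pt)
        if key not in self.tumor_pts:
            return None
        return self.sites.get(key, UNSPECIFIED_SITE)

    def tumor_display_labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.labels[p] for p in self.tumor_pts))

    def nontumor_display_labels(self) -> tuple[str, ...]:
        return tuple(
            sorted(self.labels[p] for p in set(self.paths) - self.tumor_pts)
        )

    def with_tumor_pts(self, extra: Iterable[str]) -> "MedDRAHierarchy":
        """Return a copy with ``extra`` PTs added to the tumor set."""
        added = {normalize_term(t) for t in extra}
        return MedDRAHierarchy(
            paths=self.paths,
            tumor_pts=self.tumor_pts | added,
            sites=self.sites,
            labels=self.labels,
        )


_REQUIRED_COLUMNS = ("pt", "hlt", "hlgt", "soc", "is_tumor")


def load_hierarchy(path) -> MedDRAHierarchy:
    """Load a hierarchy from delimited text (PT, HLT, HLGT, SOC, is_tumor[, site]).

    Raises
    ------
    HierarchyError
        If a PT appears twice with conflicting paths or a required column is
        missing.  An empty file yields an empty hierarchy with a warning.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("hierarchy file %s is empty", path)
        return MedDRAHierarchy(paths={}, tumor_pts=frozenset())
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise HierarchyError(f"hierarchy file missing columns: {missing}")
    if frame.empty:
        logger.warning("hierarchy file %s has a header but no terms", path)
        return MedDRAHierarchy(paths={}, tumor_pts=frozenset())

    paths: dict[str, tuple[str, str, str]] = {}
    labels: dict[str, str] = {}
    tumor: set[str] = set()
    sites: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        key = normalize_term(row.pt)
        pt_path = (str(row.hlt), str(row.hlgt), str(row.soc))
        if key in paths and paths[key] != pt_path:
            raise HierarchyError(
                f"PT {row.pt!r} maps to two different paths; "
                "the primary-path convention requires exactly one"
            )
        paths[key] = pt_path
        labels[key] = str(row.pt).strip()
        if str(row.is_tumor).strip() in {"1", "true", "True", "yes"}:
            tumor.add(key)
            site = getattr(row, "site", None)
            if isinstance(site, str) and site.strip():
                sites[key] = site.strip()
    return MedDRAHierarchy(
        paths=paths, tumor_pts=frozenset(tumor), sites=sites, labels=labels
    )


@lru_cache(maxsize=1)
def default_hierarchy() -> MedDRAHierarchy:
    """The bundled toy hierarchy (13 tumor PTs, 34 non-tumor PTs)."""
    ref = resources.files("pvdisprop.data").joinpath("meddra_toy.tsv")
    with resources.as_file(ref) as path:
        return load_hierarchy(path)


@dataclass
class TAEClassification:
    """Per-case tumor-event labels for a fixed case sequence.

    ``is_tae[i]`` is true iff case ``i``'s reactions intersect the tumor PT
    set; ``matched[i]`` holds the matching tumor PTs (display labels, in
    reaction order).  ``unknown_terms`` counts reaction PTs absent from the
    hierarchy — they are classified non-tumor, never an error.
    """

    is_tae: list[bool]
    matched: list[tuple[str, ...]]
    unknown_terms: Counter
    n_cases: int

    @property
    def n_tae(self) -> int:
        return sum(self.is_tae)

    @property
    def n_non_tae(self) -> int:
        return self.n_cases - self.n_tae

    def tae_indices(self) -> list[int]:
        return [i for i, flag in enumerate(self.is_tae) if flag]


def classify_cases(cases: Sequence, hierarchy: MedDRAHierarchy) -> TAEClassification:
    """Label every case as tumor-related or not.

    ``cases`` may be any sequence of objects with a ``reactions`` attribute
    (sequence of PT labels).
    """
    tumor = hierarchy.tumor_pts
    known = hierarchy.paths
    is_tae: list[bool] = []
    matched: list[tuple[str, ...]] = []
    unknown: Counter = Counter()
    for case in cases:
        hits = []
        for pt in case.reactions:
            key = normalize_term(pt)
            if key in tumor:
                hits.append(hierarchy.labels.get(key, pt))
            elif key not in known:
                unknown[pt] += 1
        is_tae.append(bool(hits))
        matched.append(tuple(hits))
    if unknown:
        logger.info(
            "%d reaction mentions used %d PTs absent from the hierarchy; "
            "classified non-tumor",
            sum(unknown.values()),
            len(unknown),
        )
    return TAEClassification(
        is_tae=is_tae, matched=matched, unknown_terms=unknown, n_cases=len(cases)
    )
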