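"""Aggregation of deconvolution cell-type scores into IHC-equivalent composites.

Deconvolution methods report fine-grained immune cell subsets, while
quantitative immunohistology reports densities for single markers (CD3 for
all T cells, CD8 for cytotoxic T cells, CD68 for macrophages).  To compare
the two, the subset scores that express a given marker are combined into one
composite score per marker.  The default combination rule is a sum: combined
groups of abundances or enrichments are additive in cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import DeconvolutionResult

MARKERS = ("CD3", "CD8", "CD68")

#: the 22 immune cell types of the CIBERSORT LM22 signature matrix
LM22_CATALOG = (
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
)

#: the 64 cell types scored by xCELL enrichment analysis
XCELL64_CATALOG = (
    "aDC",
    "Adipocytes",
    "Astrocytes",
    "B-cells",
    "Basophils",
    "CD4+ memory T-cells",
    "CD4+ naive T-cells",
    "CD4+ T-cells",
    "CD4+ Tcm",
    "CD4+ Tem",
    "CD8+ naive T-cells",
    "CD8+ T-cells",
    "CD8+ Tcm",
    "CD8+ Tem",
    "cDC",
    "Chondrocytes",
    "Class-switched memory B-cells",
    "CLP",
    "CMP",
    "DC",
    "Endothelial cells",
    "Eosinophils",
    "Epithelial cells",
    "Erythrocytes",
    "Fibroblasts",
    "GMP",
    "Hepatocytes",
    "HSC",
    "iDC",
    "Keratinocytes",
    "ly Endothelial cells",
    "Macrophages",
    "Macrophages M1",
    "Macrophages M2",
    "Mast cells",
    "Megakaryocytes",
    "Melanocytes",
    "Memory B-cells",
    "MEP",
    "Mesangial cells",
    "Monocytes",
    "MPP",
    "MSC",
    "mv Endothelial cells",
    "Myocytes",
    "naive B-cells",
    "Neurons",
    "Neutrophils",
    "NK cells",
    "NKT",
    "Osteoblast",
    "pDC",
    "Pericytes",
    "Plasma cells",
    "Platelets",
    "Preadipocytes",
    "pro B-cells",
    "Sebocytes",
    "Skeletal muscle",
    "Smooth muscle",
    "Tgd cells",
    "Th1 cells",
    "Th2 cells",
    "Tregs",
)

_CIBERSORT_MARKERS: dict[str, tuple[str, ...]] = {
    "CD3": (
        "T cells CD8",
        "T cells CD4 naive",
        "T cells CD4 memory resting",
        "T cells CD4 memory activated",
        "T cells follicular helper",
        "T cells regulatory (Tregs)",
        "T cells gamma delta",
    ),
    "CD8": ("T cells CD8",),
    "CD68": ("Macrophages M0", "Macrophages M1", "Macrophages M2"),
}

# One consistent reading of the interleaved published layout: NKT is counted
# in the CD3 group (NKT cells express CD3), overridable by a mapping file.
_XCELL_MARKERS: dict[str, tuple[str, ...]] = {
    "CD3": (
        "CD4+ memory T-cells",
        "CD4+ naive T-cells",
        "CD4+ T-cells",
        "CD4+ Tcm",
        "CD4+ Tem",
        "CD8+ naive T-cells",
        "CD8+ T-cells",
        "CD8+ Tcm",
        "CD8+ Tem",
        "Tregs",
        "Th1 cells",
        "Th2 cells",
        "Tgd cells",
        "NKT",
    ),
    "CD8": ("CD8+ naive T-cells", "CD8+ T-cells", "CD8+ Tcm", "CD8+ Tem"),
    "CD68": ("Macrophages", "Macrophages M1", "Macrophages M2"),
}


@dataclass
class CompositeMapping:
    """Map from IHC marker to the deconvolution cell types that express it."""

    method: str
    markers: dict[str, tuple[str, ...]]
    catalog: tuple[str, ...]

    def __post_init__(self) -> None:
        cat = set(self.catalog)
        for marker, constituents in self.markers.items():
            if not constituents:
                raise ValueError(f"marker {marker}: empty constituent list")
            if len(set(constituents)) != len(constituents):
                raise ValueError(f"marker {marker}: duplicate constituents")
            missing = [c for c in constituents if c not in cat]
            if missing:
                raise ValueError(f"marker {marker}: constituents not in catalog: {missing}")

    def constituents(self, marker: str) -> tuple[str, ...]:
        try:
            return self.markers[marker]
        except KeyError:
            raise KeyError(f"marker {marker!r} not defined; have {sorted(self.markers)}") from None


@dataclass
class CompositeScores:
    """Marker x sample composite matrix plus provenance of its construction."""

    values: pd.DataFrame
    mapping: CompositeMapping
    rule: str
    provenance: dict = field(default_factory=dict)


def default_mapping(method: str) -> CompositeMapping:
    """Built-in marker-to-cell-type mappings for the two standard catalogs.

    ``cibersort_lm22``: CD3 = the seven T-cell subsets of LM22, CD8 = the
    single CD8 subset, CD68 = the three macrophage polarization states.
    ``xcell64``: CD3 = fourteen CD3-expressing subsets (all CD4/CD8
    populations, Tregs, Th1/Th2, gamma-delta, NKT), CD8 = the four CD8
    subsets, CD68 = the three macrophage types.
    """
    if method == "cibersort_lm22":
        return CompositeMapping(method, dict(_CIBERSORT_MARKERS), LM22_CATALOG)
    if method == "xcell64":
        return CompositeMapping(method, dict(_XCELL_MARKERS), XCELL64_CATALOG)
    raise ValueError(f"unknown method {method!r}; supported: ['cibersort_lm22', 'xcell64']")


def load_mapping(path, method: str = "custom", catalog: Optional[Sequence[str]] = None) -> CompositeMapping:
    """Load a marker-to-constituents mapping from a YAML/plain config file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    markers = {str(k): tuple(map(str, v)) for k, v in raw.items()}
    if catalog is None:
        catalog = tuple(dict.fromkeys(c for v in markers.values() for c in v))
    return CompositeMapping(method, markers, tuple(catalog))


def _canonical(name: str, aliases: Optional[Mapping[str, str]]) -> str:
    name = name.strip()
    if aliases:
        return aliases.get(name, name)
    return name


def build_composites(
    decon: DeconvolutionResult,
    mapping: CompositeMapping,
    rule: str = "sum",
    strict: bool = True,
    aliases: Optional[Mapping[str, str]] = None,
) -> CompositeScores:
    """Aggregate constituent cell-type scores into one composite per marker.

    Parameters
    ----------
    decon:
        Cell type x sample score matrix.
    mapping:
        Which cell types express each IHC marker.
    rule:
        ``sum`` (default; combined abundances add) or ``mean``.
    strict:
        When True (default) every constituent must be present in the score
        matrix; when False, absent constituents are skipped with a log entry.
    aliases:
        Optional dialect map applied to the score matrix row names before
        matching (e.g. ``{"T.cells.CD8": "T cells CD8"}``).  Matching is
        exact after trimming surrounding whitespace.
    """
    if rule not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    scores = decon.scores.copy()
    scores.index = [_canonical(n, aliases) for n in scores.index]
    rows = {}
    used: dict[str, list[str]] = {}
    for marker, constituents in mapping.markers.items():
        present = [c for c in constituents if c in scores.index]
        absent = [c for c in constituents if c not in scores.index]
        if absent and strict:
            raise KeyError(f"marker {marker}: constituents absent from deconvolution output: {absent}")
        if not present:
            raise KeyError(f"marker {marker}: no constituent present in deconvolution output")
        block = scores.loc[present]
        rows[marker] = block.sum(axis=0) if rule == "sum" else block.mean(axis=0)
        used[marker] = present
    values = pd.DataFrame(rows).T
    values.index.name = "marker"
    return CompositeScores(
        values=values,
        mapping=mapping,
        rule=rule,
        provenance={"method": decon.method, "semantics": decon.semantics, "constituents_used": used},
    )
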