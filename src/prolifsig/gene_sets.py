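"""Immune-function gene-set catalog and GMT file handling.

The targeted panel's ~394 genes are organized into 41 immune-function
categories. Three categories with published membership ship as a packaged
fixture: the 10-gene cell-proliferation signature, antigen processing
(HLA/CD74 genes) and dendritic cell markers. The CD8 T-cell transcripts
CD8A/CD8B are used for cold-tumor calls.

Gene-set files use the GMT dialect: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Mapping, Sequence

GeneSetCatalog = Dict[str, List[str]]

#: The 10-gene proliferation signature (cell-cycle / mitosis markers).
PROLIFERATION_GENES = ("BUB1", "CCNB2", "CDK1", "CDKN3", "FOXM1",
                       "KIAA0101", "MAD2L1", "MELK", "MKI67", "TOP2A")

#: CD8-coding transcripts used for the cold-tumor rank.
CD8_GENES = ("CD8A", "CD8B")

PROLIFERATION_CATEGORY = "proliferation"


def read_gmt(path) -> GeneSetCatalog:
    """Parse a GMT file into an ordered name -> gene-list mapping."""
    catalog: GeneSetCatalog = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 f"description and >= 1 gene")
            name = fields[0]
            genes = [g.strip().upper() for g in fields[2:] if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            if name in catalog:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            catalog[name] = genes
    return catalog


def write_gmt(catalog: Mapping[str, Sequence[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def validate_catalog(catalog: Mapping[str, Sequence[str]]) -> None:
    """Check catalog invariants: non-empty sets, uppercase symbols."""
    if not catalog:
        raise ValueError("empty gene-set catalog")
    for name, genes in catalog.items():
        if not genes:
            raise ValueError(f"category {name!r} has no genes")
        lower = [g for g in genes if g != g.upper()]
        if lower:
            raise ValueError(f"category {name!r} has non-uppercase symbols: {lower}")
    prolif = catalog.get(PROLIFERATION_CATEGORY)
    if prolif is not None and len(prolif) != 10:
        raise ValueError("the proliferation signature must have exactly 10 genes")


def printed_function_sets() -> GeneSetCatalog:
    """The three immune-function categories with published gene membership."""
    path = resources.files("prolifsig.data") / "printed_function_sets.gmt"
    with resources.as_file(path) as p:
        return read_gmt(p)
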