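"""Gene-panel configuration: established vs candidate predisposition genes
and named gene sets (e.g. the MRN double-strand-break-repair complex)."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping

import yaml

GeneClass = str  # "established" | "candidate"

_VALID_CLASSES = ("established", "candidate")


@dataclass(frozen=True)
class GenePanel:
    """Map of gene symbol -> class, plus named gene sets.

    The class split mirrors clinical practice: ``established`` genes have
    high-to-moderate penetrance with prognostic/predictive potential,
    ``candidate`` genes have uncertain clinical effects.
    """

    genes: Mapping[str, GeneClass]
    gene_sets: Mapping[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, cls in self.genes.items():
            if cls not in _VALID_CLASSES:
                raise ValueError(
                    f"gene {gene!r} has class {cls!r}; expected one of {_VALID_CLASSES}"
                )
        for name, members in self.gene_sets.items():
            missing = [g for g in members if g not in self.genes]
            if missing:
                raise ValueError(
                    f"gene set {name!r} references genes absent from the panel: {missing}"
                )

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def class_of(self, gene: str) -> GeneClass:
        try:
            return self.genes[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} is not in the panel") from None

    def genes_in_class(self, cls: GeneClass) -> List[str]:
        if cls not in _VALID_CLASSES:
            raise ValueError(f"unknown gene class {cls!r}")
        return sorted(g for g, c in self.genes.items() if c == cls)

    @classmethod
    def from_dict(cls, data: Mapping) -> "GenePanel":
        genes = dict(data.get("genes", {}))
        gene_sets = {k: list(v) for k, v in dict(data.get("gene_sets", {})).items()}
        return cls(genes=genes, gene_sets=gene_sets)

    def to_dict(self) -> Dict:
        return {
            "genes": dict(self.genes),
            "gene_sets": {k: list(v) for k, v in self.gene_sets.items()},
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenePanel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "genes" not in data:
            raise ValueError(f"panel file {path} must define a 'genes' mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_panel() -> GenePanel:
    """The bundled default panel.

    Contains every gene symbol named in the bundled reference analysis with
    its class, plus the MRN (MRE11-RAD50-NBN) gene set. Users extend it to
    a full screening panel (the reference design targets 226 genes) via
    their own YAML file.
    """
    ref = resources.files("cpgburden.data").joinpath("default_panel.yaml")
    with resources.as_file(ref) as path:
        return GenePanel.from_yaml(path)
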