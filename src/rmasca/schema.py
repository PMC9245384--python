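"""Variable panels for NMR serum profiling.

Two fixed panels are supported: the lipoprotein subfraction panel (100
variables: triglycerides, free/esterified cholesterol and phospholipids in
serum, the four main lipoprotein classes and their density subclasses, plus
apolipoproteins A1/A2/B where the assay reports them) and the small-molecule
panel (26 integrated peaks: 24 metabolites and two broad lipid signals).
Every other module indexes columns against a :class:`VariableRegistry`, so
registry order is the canonical column order throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

__all__ = [
    "VariableDescriptor",
    "VariableRegistry",
    "build_lipoprotein_registry",
    "build_metabolite_registry",
    "LIPID_ANALYTES",
    "MAIN_CLASSES",
    "SUBCLASSES",
]

#: Lipid analytes measured in every lipoprotein compartment.
LIPID_ANALYTES = ("triglycerides", "free-cholesterol", "esterified-cholesterol", "phospholipids")

#: Main lipoprotein classes, by decreasing particle size.
MAIN_CLASSES = ("VLDL", "IDL", "LDL", "HDL")

#: Density subclasses within the main classes (IDL has none).
SUBCLASSES = tuple(
    [f"VLDL{i}" for i in range(1, 6)]
    + [f"LDL{i}" for i in range(1, 7)]
    + [f"HDL{i}" for i in range(1, 5)]
)

_ANALYTE_ABBREV = {
    "triglycerides": "TG",
    "free-cholesterol": "FC",
    "esterified-cholesterol": "CE",
    "phospholipids": "PL",
    "apo-A1": "ApoA1",
    "apo-A2": "ApoA2",
    "apo-B": "ApoB",
    "metabolite-peak": "peak",
}

# Compartments in which the assay reports each apolipoprotein.
_APO_PLACEMENTS = {
    "apo-A1": ("serum-total", "HDL", "HDL1", "HDL2", "HDL3", "HDL4"),
    "apo-A2": ("serum-total", "HDL", "HDL1", "HDL2", "HDL3", "HDL4"),
    "apo-B": ("serum-total", "LDL", "LDL1", "LDL2", "LDL3", "LDL4", "LDL5", "LDL6"),
}


@dataclass(frozen=True)
class VariableDescriptor:
    """One measured variable: a compartment/analyte pair with units.

    ``ppm_anchor`` is the chemical-shift position for integrated peaks and is
    only set for the metabolite panel. ``canonical`` is False for placeholder
    metabolites whose identity is not fixed by the assay description.
    """

    name: str
    compartment: str
    analyte: str
    units: str
    ppm_anchor: float | None = None
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.analyte in _APO_PLACEMENTS and self.compartment not in _APO_PLACEMENTS[self.analyte]:
            raise ValueError(
                f"{self.analyte} is not reported in compartment {self.compartment!r}"
            )


def _compartment_tag(compartment: str) -> str:
    return "SERUM" if compartment == "serum-total" else compartment


@dataclass(frozen=True)
class VariableRegistry:
    """Ordered, immutable collection of variable descriptors.

    The order of ``variables`` defines column order for datasets, design-cell
    effect matrices, loadings and all on-disk outputs.
    """

    panel: str
    variables: tuple[VariableDescriptor, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names in registry: {dupes}")
        # Peak variables are distinguished by name alone; for lipoprotein
        # parameters the compartment/analyte pair must be unique.
        pairs = [
            (v.compartment, v.analyte)
            for v in self.variables
            if not v.analyte.endswith("peak")
        ]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate compartment/analyte pair in registry")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self) -> Iterator[VariableDescriptor]:
        return iter(self.variables)

    def __getitem__(self, name: str) -> VariableDescriptor:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(name) from None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"panel": self.panel, "variables": [asdict(v) for v in self.variables]}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "VariableRegistry":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls(
            panel=payload["panel"],
            variables=tuple(VariableDescriptor(**v) for v in payload["variables"]),
        )


def build_lipoprotein_registry() -> VariableRegistry:
    """Full 100-variable lipoprotein subfraction panel.

    4 lipid analytes in serum, 4 main classes and 15 density subclasses
    (80 variables), plus 20 apolipoprotein variables (serum A1/A2/B, LDL B,
    HDL A1/A2, HDL1-4 A1/A2, LDL1-6 B). All concentrations in mg/dL.
    """
    out: list[VariableDescriptor] = []
    compartments = ("serum-total",) + MAIN_CLASSES + SUBCLASSES
    for comp in compartments:
        for analyte in LIPID_ANALYTES:
            out.append(
                VariableDescriptor(
                    name=f"{_compartment_tag(comp)}_{_ANALYTE_ABBREV[analyte]}",
                    compartment=comp,
                    analyte=analyte,
                    units="mg/dL",
                )
            )
    for apo, comps in _APO_PLACEMENTS.items():
        for comp in comps:
            out.append(
                VariableDescriptor(
                    name=f"{_compartment_tag(comp)}_{_ANALYTE_ABBREV[apo]}",
                    compartment=comp,
                    analyte=apo,
                    units="mg/dL",
                )
            )
    return VariableRegistry(panel="lipoprotein", variables=tuple(out))


# Metabolites explicitly reported by the assay/results: (name, ppm anchor or None).
_CANONICAL_METABOLITES: tuple[tuple[str, float | None], ...] = (
    ("lysine", None),
    ("glutamate", None),
    ("glutamine", None),
    ("formate", None),
    ("lactate", None),
    ("glucose", None),
    ("creatinine", None),
    ("glycine", None),
    ("creatine", None),
    ("2-methylglutarate", None),
    ("3-hydroxybutyrate", None),
    ("acetate", None),
    ("alanine", 1.47),
)

# Placeholder identities completing the 24-metabolite panel; the assay reports
# 24 metabolite peaks but does not enumerate all of them, so the remainder are
# filled with common serum NMR metabolites and flagged non-canonical.
_PLACEHOLDER_METABOLITES = (
    "valine",
    "leucine",
    "isoleucine",
    "tyrosine",
    "phenylalanine",
    "histidine",
    "threonine",
    "pyruvate",
    "citrate",
    "acetone",
    "methionine",
)


def build_metabolite_registry() -> VariableRegistry:
    """26-peak small-molecule panel: 24 metabolites plus two lipid signals.

    The lipid peaks are the methyl (-CH3) signal at 0.85 ppm (``lipid1``) and
    the methylene (-CH2-) signal at 1.57 ppm (``lipid2``). Metabolites not
    fixed by the assay description carry ``canonical=False``. Units are mM.
    """
    out: list[VariableDescriptor] = []
    for name, ppm in _CANONICAL_METABOLITES:
        out.append(
            VariableDescriptor(
                name=name, compartment="serum-total", analyte="metabolite-peak",
                units="mM", ppm_anchor=ppm,
            )
        )
    for name in _PLACEHOLDER_METABOLITES:
        out.append(
            VariableDescriptor(
                name=name, compartment="serum-total", analyte="metabolite-peak",
                units="mM", canonical=False,
            )
        )
    out.append(
        VariableDescriptor(
            name="lipid1", compartment="serum-total", analyte="lipid-peak",
            units="mM", ppm_anchor=0.85,
        )
    )
    out.append(
        VariableDescriptor(
            name="lipid2", compartment="serum-total", analyte="lipid-peak",
            units="mM", ppm_anchor=1.57,
        )
    )
    return VariableRegistry(panel="metabolite", variables=tuple(out))
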