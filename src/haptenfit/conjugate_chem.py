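"""Peptide-design utilities for conjugate vaccines.

Covers the chemistry arithmetic the rest of the pipeline needs:

* peptide masses (average and monoisotopic) from one-letter sequences with
  terminal modifications, following the conjugate-peptide design pattern
  ``Ac-(epitope + linker) x repeats + Cys``;
* the ladder spacing Delta — the neutral mass a carrier gains per conjugated
  peptide, i.e. peptide mass plus the crosslinker remnant;
* strict percent identity between epitope homologs;
* predicted neutral masses of the conjugate species carrying 0..n peptides.

The worked chemistry is lysine-amine / cysteine-thiol coupling through the
heterobifunctional crosslinker SBAP (succinimidyl 3-(bromoacetamido)
propionate): the NHS ester acylates a solvent-accessible lysine (losing
N-hydroxysuccinimide), then the bromoacetamide alkylates the peptide's
C-terminal cysteine thiol (losing HBr).  Unreacted activated sites are
capped with free L-cysteine through the same thioether chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from .errors import ChemistryError

MassKind = Literal["average", "monoisotopic"]

# Amino-acid residue masses (Da), average and monoisotopic, from the standard
# residue-mass table distributed with the AAindex/ExPASy compilations.
RESIDUE_MASS_AVERAGE: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
RESIDUE_MASS_MONO: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = {"average": 18.01528, "monoisotopic": 18.010565}
ACETYL = {"average": 42.0367, "monoisotopic": 42.010565}
#: free acid -> amide at the C terminus (replace OH by NH2)
AMIDE = {"average": -0.98476, "monoisotopic": -0.984016}

# Average atomic weights for formula arithmetic on small linker molecules.
_ATOM_AVG = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06, "Br": 79.904}
_ATOM_MONO = {
    "C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221,
    "S": 31.97207069, "Br": 78.9183376,
}


def _formula_mass(formula: dict[str, int], kind: MassKind) -> float:
    table = _ATOM_AVG if kind == "average" else _ATOM_MONO
    return sum(table[el] * n for el, n in formula.items())


# IL-17RB inactivation-site (IRIS) epitope homologs, residues 19-31 of the
# receptor ectodomain (UniProt A3KN55 / Q9JIP3 / Q9NRM6).
BOVINE_IRIS = "VRHTLTPGDLRDL"
MOUSE_IRIS = "VQHTLTPGDLRDL"
HUMAN_IRIS = "LQHDLIPGDLRDL"


@dataclass
class PeptideDesign:
    """A conjugate peptide: N-acetylated epitope repeats plus terminal Cys.

    The synthesized peptide is assembled as
    ``(epitope + linker) * repeats + terminal`` — e.g. one or two copies of
    a 13-residue epitope joined by a GG linker and ending in the cysteine
    that carries the thiol used for conjugation.
    """

    epitope_sequence: str
    repeats: int = 1
    linker: str = "GG"
    terminal: str = "C"
    n_term_mod: Literal["acetyl", "none"] = "acetyl"
    c_term: Literal["free_acid", "amide"] = "free_acid"
    name: str = ""

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ChemistryError(f"repeats must be >= 1, got {self.repeats}")
        for label, seq in (
            ("epitope", self.epitope_sequence),
            ("linker", self.linker),
            ("terminal", self.terminal),
        ):
            bad = set(seq) - set(RESIDUE_MASS_AVERAGE)
            if bad:
                raise ChemistryError(
                    f"invalid residue letter(s) {sorted(bad)} in {label} "
                    f"sequence {seq!r}"
                )

    @property
    def full_sequence(self) -> str:
        return (self.epitope_sequence + self.linker) * self.repeats + self.terminal


def mouse_iris_design(repeats: int = 1) -> PeptideDesign:
    """The murine IRIS conjugate peptide (1 repeat: IRIS1; 2: IRIS2)."""
    return PeptideDesign(MOUSE_IRIS, repeats=repeats, name=f"mIRIS{repeats}")


def human_iris_design(repeats: int = 1) -> PeptideDesign:
    """The human IRIS conjugate peptide (1 repeat: IRIS1; 2: IRIS2)."""
    return PeptideDesign(HUMAN_IRIS, repeats=repeats, name=f"hIRIS{repeats}")


@dataclass
class ConjugationChemistry:
    """Mass bookkeeping of the conjugation chemistry.

    linker_remnant_mass :
        Da added to the carrier per conjugated peptide *beyond* the peptide
        mass (crosslinker remnant after coupling and leaving-group losses).
    capping_adduct_mass :
        Da added per capped unreacted activated site, relative to the bare
        carrier.
    n_activatable_sites :
        Number of solvent-accessible lysines available for activation
        (~20 of 39 for the CRM197 carrier).
    """

    linker_remnant_mass: float
    capping_adduct_mass: float = 0.0
    n_activatable_sites: int = 20
    capping_policy: Literal["cap_remaining", "none"] = "cap_remaining"

    def __post_init__(self) -> None:
        if self.linker_remnant_mass < 0 or self.capping_adduct_mass < 0:
            raise ChemistryError("adduct masses must be >= 0")
        if self.n_activatable_sites < 1:
            raise ChemistryError("n_activatable_sites must be >= 1")


def sbap_chemistry(
    n_activatable_sites: int = 20,
    capping_policy: Literal["cap_remaining", "none"] = "cap_remaining",
    kind: MassKind = "average",
) -> ConjugationChemistry:
    """SBAP lysine/cysteine coupling constants from formula arithmetic.

    Per conjugated peptide the carrier gains the 3-(bromoacetamido)propionyl
    remnant: acid (C5H8BrNO3) minus H2O (amide bond) minus HBr (thioether),
    i.e. C5H5NO2 ~ 111.10 Da average.  A capped site gains the same acyl
    remnant plus free cysteine minus HBr (~232.25 Da average).
    """
    acid = _formula_mass({"C": 5, "H": 8, "Br": 1, "N": 1, "O": 3}, kind)
    h2o = _formula_mass({"H": 2, "O": 1}, kind)
    hbr = _formula_mass({"H": 1, "Br": 1}, kind)
    cys = _formula_mass({"C": 3, "H": 7, "N": 1, "O": 2, "S": 1}, kind)
    return ConjugationChemistry(
        linker_remnant_mass=acid - h2o - hbr,
        capping_adduct_mass=acid - h2o + cys - hbr,
        n_activatable_sites=n_activatable_sites,
        capping_policy=capping_policy,
    )


def peptide_mass(design: PeptideDesign, kind: MassKind = "average") -> float:
    """Neutral mass of the full synthesized peptide in Da.

    Sum of residue masses plus one water, plus terminal-modification deltas
    (N-acetylation +42.037 average / +42.0106 monoisotopic; C-terminal
    amidation -0.985).
    """
    if kind not in ("average", "monoisotopic"):
        raise ChemistryError(f"unknown mass kind {kind!r}")
    table = RESIDUE_MASS_AVERAGE if kind == "average" else RESIDUE_MASS_MONO
    seq = design.full_sequence
    mass = sum(table[r] for r in seq) + WATER[kind]
    if design.n_term_mod == "acetyl":
        mass += ACETYL[kind]
    if design.c_term == "amide":
        mass += AMIDE[kind]
    return mass


def ladder_spacing(
    design: PeptideDesign,
    chem: ConjugationChemistry,
    kind: MassKind = "average",
) -> float:
    """Neutral mass increment Delta per conjugated peptide.

    ``Delta = peptide_mass + linker_remnant_mass`` — what one additional
    peptide adds to a carrier at an uncapped activated site.  Under the
    ``cap_remaining`` policy each conjugation also displaces one cysteine
    cap, so the *observed* spacing between neighbouring ladder species is
    ``Delta - capping_adduct_mass`` (see :func:`predict_species_masses`).
    """
    return peptide_mass(design, kind) + chem.linker_remnant_mass


def observed_ladder_spacing(
    design: PeptideDesign,
    chem: ConjugationChemistry,
    kind: MassKind = "average",
) -> float:
    """Spacing between neighbouring species under the capping policy."""
    delta = ladder_spacing(design, chem, kind)
    if chem.capping_policy == "cap_remaining":
        return delta - chem.capping_adduct_mass
    return delta


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Strict percent identity of two gap-free, equal-length sequences.

    100 x (matching positions) / length.  This is identity, not a
    substitution-matrix similarity: conservative substitutions count as
    mismatches.
    """
    if len(seq_a) != len(seq_b):
        raise ChemistryError(
            f"length mismatch: {len(seq_a)} vs {len(seq_b)} residues"
        )
    if len(seq_a) == 0:
        raise ChemistryError("empty sequences")
    matches = sum(a == b for a, b in zip(seq_a, seq_b))
    return 100.0 * matches / len(seq_a)


def predict_species_masses(
    carrier_mass: float,
    design: PeptideDesign,
    chem: ConjugationChemistry,
    n_range: tuple[int, int],
    kind: MassKind = "average",
) -> list[tuple[int, float]]:
    """Neutral masses of conjugate species carrying ``n_min..n_max`` peptides.

    With ``capping_policy == "cap_remaining"`` every activated but
    unconjugated site carries a cysteine cap, so

        mass(n) = carrier + n * Delta + (n_sites - n) * cap_adduct

    and the ladder spacing seen in a spectrum is ``Delta - cap_adduct``.
    With policy ``"none"`` no caps are added and the spacing is exactly
    ``Delta``.
    """
    n_min, n_max = n_range
    if n_min < 0 or n_max < n_min:
        raise ChemistryError(f"invalid load range {n_range}")
    if n_max > chem.n_activatable_sites:
        raise ChemistryError(
            f"n_max={n_max} exceeds {chem.n_activatable_sites} activatable sites"
        )
    delta = ladder_spacing(design, chem, kind)
    out = []
    for n in range(n_min, n_max + 1):
        mass = carrier_mass + n * delta
        if chem.capping_policy == "cap_remaining":
            mass += (chem.n_activatable_sites - n) * chem.capping_adduct_mass
        out.append((n, mass))
    return out


def read_designs_fasta(path, **kwargs) -> list[PeptideDesign]:
    """Read epitope sequences from FASTA; one single-repeat design each."""
    path = Path(path)
    designs = []
    for record in SeqIO.parse(str(path), "fasta"):
        designs.append(
            PeptideDesign(str(record.seq).upper(), name=record.id, **kwargs)
        )
    if not designs:
        raise ChemistryError(f"{path}: no FASTA records")
    return designs


def identity_matrix(sequences: Sequence[str]) -> list[list[float]]:
    """Pairwise strict-identity matrix (percent) for equal-length sequences."""
    return [
        [percent_identity(a, b) for b in sequences] for a in sequences
    ]
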