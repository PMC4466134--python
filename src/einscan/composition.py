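"""Protein composition, hydrogen classes and neutron scattering budgets.

Incoherent neutron scattering from a hydrated protein powder is dominated by
hydrogen: H makes up roughly half the atoms of a protein and its incoherent
cross-section (80.27 barn) dwarfs every other element present. This module
quantifies that statement for a concrete sequence. It

* counts the atomic composition of a polypeptide chain,
* splits hydrogens into three classes — methyl H, non-methyl non-exchangeable
  H, and exchangeable H (bonded to N, O or S, replaced by D in D2O) — which
  fixes the population fractions a1/a2 of the bimodal elastic model, and
* computes incoherent/coherent scattering budgets for the hydrated, (partly)
  deuterium-exchanged powder, including the solvent-D2O share and the share
  of hydrogens contributed by a bound ligand.

Chains are treated with explicit termini: the composition of an n-residue
chain equals the sum of the free amino-acid formulas minus (n-1) waters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

from Bio import SeqIO

__all__ = [
    "AtomicComposition",
    "HydrogenClasses",
    "ScatteringBudget",
    "CROSS_SECTIONS",
    "CROSS_SECTION_TABLE_VERSION",
    "PALMITATE",
    "read_sequence",
    "count_atoms",
    "classify_hydrogens",
    "scattering_budget",
    "bundled_sequence_path",
]

# ---------------------------------------------------------------------------
# residue chemistry tables
# ---------------------------------------------------------------------------

#: free amino-acid molecular formulas (C, H, N, O, S), neutral species
_FREE_AA_FORMULA = {
    "A": (3, 7, 1, 2, 0),
    "R": (6, 14, 4, 2, 0),
    "N": (4, 8, 2, 3, 0),
    "D": (4, 7, 1, 4, 0),
    "C": (3, 7, 1, 2, 1),
    "E": (5, 9, 1, 4, 0),
    "Q": (5, 10, 2, 3, 0),
    "G": (2, 5, 1, 2, 0),
    "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0),
    "L": (6, 13, 1, 2, 0),
    "K": (6, 14, 2, 2, 0),
    "M": (5, 11, 1, 2, 1),
    "F": (9, 11, 1, 2, 0),
    "P": (5, 9, 1, 2, 0),
    "S": (3, 7, 1, 3, 0),
    "T": (4, 9, 1, 3, 0),
    "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0),
    "V": (5, 11, 1, 2, 0),
}

#: side-chain hydrogens bonded to N, O or S (neutral side chains)
_SIDECHAIN_EXCHANGEABLE = {
    "R": 4, "N": 2, "D": 1, "C": 1, "E": 1, "Q": 2, "H": 1, "K": 2,
    "S": 1, "T": 1, "W": 1, "Y": 1,
}

#: CH3 groups per residue side chain
_METHYL_GROUPS = {"A": 1, "V": 2, "L": 2, "I": 2, "T": 1, "M": 1}

#: backbone N/O-bonded H of the FREE amino acid: NH2 (2) + COOH (1); Pro NH (1) + COOH (1)
_BACKBONE_EXCHANGEABLE_FREE = {aa: (2 if aa == "P" else 3) for aa in _FREE_AA_FORMULA}

_ATOMIC_MASS = {"H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

#: neutron cross-sections in barn. Incoherent values follow the convention of
#: the elastic-scattering literature for protein budgets (H 80.27, D 2.05,
#: N 0.5, C and O 0.001); coherent values are the standard bound-atom table.
CROSS_SECTIONS: Mapping[str, Mapping[str, float]] = {
    "H": {"incoherent": 80.27, "coherent": 1.7568},
    "D": {"incoherent": 2.05, "coherent": 5.592},
    "C": {"incoherent": 0.001, "coherent": 5.551},
    "N": {"incoherent": 0.5, "coherent": 11.01},
    "O": {"incoherent": 0.001, "coherent": 4.232},
    "S": {"incoherent": 0.007, "coherent": 1.0186},
}
CROSS_SECTION_TABLE_VERSION = "einscan-xs-1"

#: molar mass of D2O, g/mol
_D2O_MOLAR_MASS = 20.0276


@dataclass
class AtomicComposition:
    """Element counts of a molecule or chain (H counted as protium here)."""

    element_counts: Dict[str, int]
    source: str = ""

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"count for {el} must be a non-negative integer")

    @property
    def n_atoms(self) -> int:
        return int(sum(self.element_counts.values()))

    @property
    def n_hydrogen(self) -> int:
        return int(self.element_counts.get("H", 0))

    @property
    def hydrogen_fraction(self) -> float:
        return self.n_hydrogen / self.n_atoms

    @property
    def mass(self) -> float:
        """Molecular mass in g/mol."""
        return sum(_ATOMIC_MASS[el] * n for el, n in self.element_counts.items())


#: palmitate anion C16H31O2, the fatty-acid ligand of FABP-family barrels
PALMITATE = AtomicComposition({"C": 16, "H": 31, "O": 2}, source="palmitate C16H31O2")


@dataclass
class HydrogenClasses:
    """Hydrogen head-count split into the classes used by the bimodal model."""

    methyl_h: int
    nonmethyl_nonexch_h: int
    exchangeable_h: int

    def __post_init__(self) -> None:
        if min(self.methyl_h, self.nonmethyl_nonexch_h, self.exchangeable_h) < 0:
            raise ValueError("hydrogen class counts must be non-negative")
        if self.methyl_h % 3:
            raise ValueError("methyl hydrogens come in CH3 triples")

    @property
    def nonexchangeable_h(self) -> int:
        return self.methyl_h + self.nonmethyl_nonexch_h

    @property
    def total_h(self) -> int:
        return self.nonexchangeable_h + self.exchangeable_h

    @property
    def a1(self) -> float:
        """Methyl fraction of the non-exchangeable hydrogens (bimodal a1)."""
        return self.methyl_h / self.nonexchangeable_h

    @property
    def a2(self) -> float:
        return 1.0 - self.a1


@dataclass
class ScatteringBudget:
    """Incoherent/coherent budgets (barn per molecule) and derived shares."""

    incoherent_by_source: Dict[str, float]
    coherent_total: float
    solvent_incoherent_share: float
    coherent_share: float
    ligand_h_share: Optional[float] = None
    cross_section_table_version: str = CROSS_SECTION_TABLE_VERSION

    @property
    def incoherent_total(self) -> float:
        return sum(self.incoherent_by_source.values())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_sequence(fasta_source) -> str:
    """Read a single-record FASTA and return the validated one-letter sequence.

    ``fasta_source`` may be a path, an open text handle, or a string holding
    FASTA text. Lowercase letters are upcased; anything outside the 20
    standard amino acids is rejected.
    """
    if isinstance(fasta_source, str) and fasta_source.lstrip().startswith(">"):
        handle = io.StringIO(fasta_source)
    elif hasattr(fasta_source, "read"):
        handle = fasta_source
    else:
        handle = open(fasta_source)

    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if handle is not fasta_source and hasattr(handle, "close"):
            handle.close()

    if len(records) == 0:
        raise ValueError("no FASTA record found")
    if len(records) > 1:
        raise ValueError(f"expected a single FASTA record, found {len(records)}")

    seq = str(records[0].seq).upper()
    bad = sorted(set(seq) - set(_FREE_AA_FORMULA))
    if bad:
        raise ValueError(f"non-standard residue letters: {''.join(bad)}")
    if not seq:
        raise ValueError("empty sequence")
    return seq


def bundled_sequence_path() -> str:
    """Path to the bundled SYNTHETIC stand-in sequence (see its FASTA header).

    The stand-in is a 132-residue chain whose amino-acid composition was
    constructed to match the published composition characteristics of human
    myelin P2 (hydrogen ~50% of atoms, methyl fraction a1 = 0.26 of
    non-exchangeable H); it is not the database record, and users analysing
    real data should supply their own FASTA.
    """
    from importlib.resources import files

    return str(files("einscan.data") / "p2_human_synthetic.fasta")


def count_atoms(sequence: str) -> AtomicComposition:
    """Atomic composition of a polypeptide chain with explicit termini.

    Equals the sum of free amino-acid formulas minus one water per peptide
    bond, i.e. the N-terminal amine and C-terminal carboxyl keep their
    hydrogens.
    """
    if not sequence:
        raise ValueError("empty sequence")
    c = h = n = o = s = 0
    for aa in sequence:
        try:
            cc, hh, nn, oo, ss = _FREE_AA_FORMULA[aa]
        except KeyError:
            raise ValueError(f"unknown residue letter {aa!r}") from None
        c += cc; h += hh; n += nn; o += oo; s += ss
    n_bonds = len(sequence) - 1
    h -= 2 * n_bonds
    o -= n_bonds
    counts = {"C": c, "H": h, "N": n, "O": o}
    if s:
        counts["S"] = s
    return AtomicComposition(counts, source=f"chain of {len(sequence)} residues")


def classify_hydrogens(sequence: str) -> HydrogenClasses:
    """Split the chain's hydrogens into methyl / non-methyl / exchangeable.

    Exchangeable = every H bonded to N, O or S (backbone amides, side-chain
    OH/NH/SH, both termini); methyl H = 3 per side-chain CH3 group (Ala 1,
    Val 2, Leu 2, Ile 2, Thr 1, Met 1); the remainder is non-methyl
    non-exchangeable (CH, CH2, aromatic CH).
    """
    comp = count_atoms(sequence)
    exch = 0
    methyl = 0
    for aa in sequence:
        exch += _BACKBONE_EXCHANGEABLE_FREE[aa] + _SIDECHAIN_EXCHANGEABLE.get(aa, 0)
        methyl += 3 * _METHYL_GROUPS.get(aa, 0)
    # each peptide bond condenses away one N-H and one O-H
    exch -= 2 * (len(sequence) - 1)
    nonmethyl = comp.n_hydrogen - exch - methyl
    return HydrogenClasses(
        methyl_h=methyl, nonmethyl_nonexch_h=nonmethyl, exchangeable_h=exch
    )


def scattering_budget(
    comp: AtomicComposition,
    classes: HydrogenClasses,
    hydration: float = 0.28,
    d2o_exchange: bool = True,
    exchange_fraction: float = 1.0,
    ligand: Optional[AtomicComposition] = None,
) -> ScatteringBudget:
    """Incoherent/coherent scattering budget of a hydrated protein powder.

    Parameters
    ----------
    comp, classes : composition and hydrogen classes of the protein chain.
    hydration : float
        g of D2O per g of protein (0.28 is typical for hydrated powders).
    d2o_exchange : bool
        If true, a fraction ``exchange_fraction`` of the exchangeable H is
        counted as D (powders equilibrated in D2O vapour).
    ligand : AtomicComposition, optional
        A bound ligand (e.g. palmitate); its H is reported as a share of ALL
        protein hydrogens.

    Notes
    -----
    The solvent share is reported within the incoherent channel; the coherent
    share is total coherent / (coherent + incoherent) over protein + exchanged
    D + solvent and is a diagnostic (it is sensitive to the exchange model).
    """
    if hydration < 0:
        raise ValueError("hydration must be >= 0")
    if not 0 <= exchange_fraction <= 1:
        raise ValueError("exchange_fraction must be in [0, 1]")

    xs = CROSS_SECTIONS
    n_exch_d = classes.exchangeable_h * (exchange_fraction if d2o_exchange else 0.0)
    n_h_remaining = comp.n_hydrogen - n_exch_d

    # solvent D2O molecules per protein molecule
    n_d2o = hydration * comp.mass / _D2O_MOLAR_MASS
    solvent_d = 2.0 * n_d2o
    solvent_o = 1.0 * n_d2o

    heavy = {el: n for el, n in comp.element_counts.items() if el != "H"}

    inc = {
        "protein_H": n_h_remaining * xs["H"]["incoherent"],
        "exchanged_D": n_exch_d * xs["D"]["incoherent"],
        "solvent_D2O": solvent_d * xs["D"]["incoherent"]
        + solvent_o * xs["O"]["incoherent"],
        "other_elements": sum(n * xs[el]["incoherent"] for el, n in heavy.items()),
    }
    coh = (
        n_h_remaining * xs["H"]["coherent"]
        + n_exch_d * xs["D"]["coherent"]
        + solvent_d * xs["D"]["coherent"]
        + solvent_o * xs["O"]["coherent"]
        + sum(n * xs[el]["coherent"] for el, n in heavy.items())
    )

    ligand_h_share = None
    if ligand is not None:
        ligand_h_share = ligand.n_hydrogen / comp.n_hydrogen
        inc["ligand_H"] = ligand.n_hydrogen * xs["H"]["incoherent"]

    inc_total = sum(inc.values())
    return ScatteringBudget(
        incoherent_by_source=inc,
        coherent_total=coh,
        solvent_incoherent_share=inc["solvent_D2O"] / inc_total,
        coherent_share=coh / (coh + inc_total),
        ligand_h_share=ligand_h_share,
    )
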