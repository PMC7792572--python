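"""Backbone-level PDB I/O and residue-pair distance extraction.

Structures are reduced to one record per residue holding the Cα position
and, when present (or virtually constructed), the Cβ position.  That is
the representation the distance-dependent pair potentials act on: only
Cα–Cα and Cβ–Cβ distances are ever scored.

Parsing and serialisation are delegated to :mod:`gemmi`; this module owns
the reduction to the Cα/Cβ model, glycine virtual-Cβ construction, and
the enumeration of pair-distance observations used to compile potentials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np

from .exceptions import GeometryError, ParameterError, PDBParseError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # nonstandard residues retained with a canonical stand-in
    "MSE": "M", "SEC": "C",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k not in ("MSE", "SEC")}

ATOM_TYPES = ("CA", "CB")
CONTACT_CLASSES = ("inter_chain", "intra_chain")

#: ideal Cα–Cβ bond length in Å
CB_BOND_LENGTH = 1.53
#: tetrahedral bond-angle cosine (N–Cα–Cβ and C–Cα–Cβ)
_TETRAHEDRAL_COS = -1.0 / 3.0


@dataclass
class ResidueRecord:
    """One residue reduced to Cα (+ optional Cβ) coordinates."""

    chain_id: str
    residue_index: int
    aa: str
    ca: np.ndarray
    cb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.cb is not None:
            self.cb = np.asarray(self.cb, dtype=float)
        if self.aa not in AA_INDEX:
            raise ParameterError(f"unknown amino-acid code {self.aa!r}")


@dataclass
class StructureModel:
    """Ordered chains of residue records, keyed by chain id."""

    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for cid, residues in self.chains.items():
            indices = [r.residue_index for r in residues]
            if indices != sorted(indices):
                raise ParameterError(f"chain {cid}: residues not in ascending order")
            for r in residues:
                key = (cid, r.residue_index)
                if key in seen:
                    raise ParameterError(f"duplicate residue {key}")
                seen.add(key)

    def residues(self) -> Iterator[ResidueRecord]:
        for residues in self.chains.values():
            yield from residues

    def residue(self, chain_id: str, residue_index: int) -> ResidueRecord:
        for r in self.chains[chain_id]:
            if r.residue_index == residue_index:
                return r
        raise KeyError((chain_id, residue_index))

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chains[chain_id])

    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def subset(self, chain_ids: Sequence[str]) -> "StructureModel":
        return StructureModel(
            chains={c: [replace(r) for r in self.chains[c]] for c in chain_ids if c in self.chains},
            source_id=self.source_id,
        )


@dataclass(frozen=True)
class PairObservation:
    """A single residue-pair distance, canonically ordered (aa_a <= aa_b)."""

    aa_a: str
    aa_b: str
    atom_type: str
    contact_class: str
    distance: float


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Construct an ideal Cβ position from the N/Cα/C backbone atoms.

    The Cβ is placed 1.53 Å from Cα such that the N–Cα–Cβ and C–Cα–Cβ
    angles are tetrahedral, on the side of the N–Cα–C plane that gives
    L-amino-acid chirality.  Used so glycine participates in Cβ–Cβ
    scoring on the same footing as every other residue.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    u = n - ca
    v = c - ca
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("coincident backbone atoms")
    u /= nu
    v /= nv
    w = np.cross(u, v)
    nw = np.linalg.norm(w)
    if nw < 1e-8:
        raise GeometryError("collinear N/CA/C backbone atoms")
    w /= nw
    # d = alpha*(u+v) + beta*w with d.u = d.v = cos(109.47 deg), |d| = 1
    dot_uv = float(u @ v)
    alpha = _TETRAHEDRAL_COS / (1.0 + dot_uv)
    plane = alpha * (u + v)
    beta_sq = 1.0 - float(plane @ plane)
    if beta_sq <= 0.0:
        raise GeometryError("degenerate backbone geometry for virtual CB")
    # +w = (CA->N) x (CA->C) points to the L-configuration side
    d = plane + np.sqrt(beta_sq) * w
    return ca + CB_BOND_LENGTH * d


def parse_pdb(text: str, source_id: str = "", build_virtual_cb: bool = False) -> StructureModel:
    """Parse PDB-format text into the Cα/Cβ backbone model.

    Only the first MODEL of multi-model files is read; HETATM records are
    ignored except for MSE/SEC (kept as M/C); only altloc ' ' or 'A'
    atoms are used.  Residues without a Cα are dropped with a log line,
    as are residues with names outside the recognised set.

    With ``build_virtual_cb=True``, residues lacking a Cβ atom (glycine)
    get a virtual Cβ constructed from their N/Cα/C coordinates.
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no MODEL with ATOM records found")
    model = st[0]
    chains: dict[str, list[ResidueRecord]] = {}
    for chain in model:
        records: list[ResidueRecord] = []
        for res in chain:
            name = res.name.upper()
            if res.het_flag == "H" and name not in ("MSE", "SEC"):
                continue
            aa = THREE_TO_ONE.get(name)
            if aa is None:
                logger.info("dropping nonstandard residue %s %s%d", res.name, chain.name, res.seqid.num)
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.altloc not in ("\0", "A", ""):
                    continue
                if atom.name in ("N", "CA", "C", "CB") and atom.name not in atoms:
                    atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if "CA" not in atoms:
                logger.info("dropping residue without CA: %s %s%d", res.name, chain.name, res.seqid.num)
                continue
            cb = atoms.get("CB")
            if cb is None and build_virtual_cb and "N" in atoms and "C" in atoms:
                cb = virtual_cb(atoms["N"], atoms["CA"], atoms["C"])
            records.append(ResidueRecord(chain.name, res.seqid.num, aa, atoms["CA"], cb))
        if records:
            chains[chain.name] = records
    if not chains:
        raise PDBParseError("no residues with CA coordinates found")
    return StructureModel(chains=chains, source_id=source_id)


def write_pdb(model: StructureModel) -> str:
    """Serialise the Cα/Cβ model back to PDB format (3-decimal coordinates)."""
    if model.n_residues() == 0:
        raise PDBParseError("cannot write empty structure")
    st = gemmi.Structure()
    st.name = model.source_id or "mhcii3dlite"
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        if not residues:
            logger.warning("skipping empty chain %s", cid)
            continue
        chain = gemmi.Chain(cid)
        for rec in residues:
            res = gemmi.Residue()
            res.name = ONE_TO_THREE[rec.aa]
            res.seqid = gemmi.SeqId(rec.residue_index, " ")
            for name, pos in (("CA", rec.ca), ("CB", rec.cb)):
                if pos is None:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*pos)
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st.make_pdb_string()


def _canonical(aa_a: str, aa_b: str) -> tuple[str, str]:
    return (aa_a, aa_b) if aa_a <= aa_b else (aa_b, aa_a)


def extract_pair_observations(
    model: StructureModel,
    contact_class: Literal["inter_chain", "intra_chain", "both"] = "both",
    cutoff: float = 15.0,
    k_min: int = 2,
    atom_types: Sequence[str] = ATOM_TYPES,
) -> list[PairObservation]:
    """Enumerate residue-pair distance observations up to ``cutoff``.

    Inter-chain pairs join residues on different chains; intra-chain
    pairs require a residue-index separation of at least ``k_min``
    (adjacent backbone distances are covalently fixed and carry no
    signal).  Each unordered pair is emitted once, in canonical
    alphabetical amino-acid order, per atom type for which both residues
    have coordinates.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    residues = list(model.residues())
    chain_ids = np.array([r.chain_id for r in residues])
    indices = np.array([r.residue_index for r in residues])
    observations: list[PairObservation] = []
    for atom_type in atom_types:
        if atom_type == "CA":
            has = np.ones(len(residues), dtype=bool)
            coords = np.array([r.ca for r in residues]) if residues else np.empty((0, 3))
        else:
            has = np.array([r.cb is not None for r in residues])
            coords = np.array(
                [r.cb if r.cb is not None else r.ca for r in residues]
            ) if residues else np.empty((0, 3))
        for i in range(len(residues)):
            if not has[i]:
                continue
            for j in range(i + 1, len(residues)):
                if not has[j]:
                    continue
                same_chain = chain_ids[i] == chain_ids[j]
                if same_chain:
                    cls = "intra_chain"
                    if abs(int(indices[i]) - int(indices[j])) < k_min:
                        continue
                else:
                    cls = "inter_chain"
                if contact_class != "both" and cls != contact_class:
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if d > cutoff:
                    continue
                a, b = _canonical(residues[i].aa, residues[j].aa)
                observations.append(PairObservation(a, b, atom_type, cls, d))
    return observations


def filter_training_set(
    models: Iterable[StructureModel], min_len: int = 5, max_len: int = 20
) -> list[StructureModel]:
    """Keep multimers with at least one chain of length in [min_len, max_len].

    This mirrors the selection used to compile interface-focused
    potentials: complexes that contain a short peptide-like chain bound
    to at least one other chain.
    """
    if min_len > max_len:
        raise ParameterError("min_len must not exceed max_len")
    kept = []
    for m in models:
        lengths = [len(v) for v in m.chains.values()]
        if len(lengths) >= 2 and any(min_len <= L <= max_len for L in lengths):
            kept.append(m)
    return kept
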