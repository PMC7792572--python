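"""MHC II scaffold complexes and peptide backbone conformations.

A scaffold is a rigid backbone model of an MHC II heterodimer (chain A =
alpha chain, chain B = beta chain) together with one or more positioned
peptide backbone conformations whose 9-residue core sits in the binding
groove.  Alternative conformations taken from other complexes are
installed by least-squares superposition of binding-pocket Cα frames, so
threading can explore small backbone variability without remodelling
the receptor.

Scaffold files are plain PDB (chains A/B/P) with a sidecar ``.meta``
key-value text file carrying the allele, a model quality meta-score
(computed upstream, consumed here as data), the pocket residue list used
as the superposition frame, and optionally the core offset of chain P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import GeometryError, InputError, ParameterError
from .pdbio import StructureModel, parse_pdb

logger = logging.getLogger(__name__)

PEPTIDE_LENGTHS = (9, 11, 13, 15)
CORE_LENGTH = 9


@dataclass
class PeptideConformation:
    """A positioned peptide backbone with a 9-mer core window."""

    length: int
    ca: np.ndarray  # (length, 3)
    cb: np.ndarray  # (length, 3); virtual for glycine placeholders
    core_start: int
    source_id: str = ""
    source_pocket: np.ndarray | None = None  # pocket CA frame of the source complex

    def __post_init__(self) -> None:
        if self.length not in PEPTIDE_LENGTHS:
            raise ParameterError(f"peptide length {self.length} not in {PEPTIDE_LENGTHS}")
        self.ca = np.asarray(self.ca, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        if self.ca.shape != (self.length, 3) or self.cb.shape != (self.length, 3):
            raise ParameterError("backbone coordinate arrays must be (length, 3)")
        if not (0 <= self.core_start <= self.length - CORE_LENGTH):
            raise ParameterError("core window must fit inside the conformation")
        steps = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        if np.any(steps < 2.7) or np.any(steps > 4.3):
            raise ParameterError("consecutive CA distances outside [2.7, 4.3] A")
        if self.source_pocket is not None:
            self.source_pocket = np.asarray(self.source_pocket, dtype=float)


@dataclass
class Scaffold:
    """An MHC II backbone model plus positioned peptide conformations."""

    allele: str
    model: StructureModel
    conformations: list[PeptideConformation]
    pocket_residues: list[tuple[str, int]]
    meta_score: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        for cid in ("A", "B"):
            if cid not in self.model.chains:
                raise InputError(f"scaffold model missing chain {cid}")
        if not self.pocket_residues:
            raise InputError("scaffold requires a non-empty pocket residue list")

    def pocket_coords(self) -> np.ndarray:
        """Cα coordinates of the pocket residues, in metadata order."""
        return np.array(
            [self.model.residue(c, i).ca for (c, i) in self.pocket_residues]
        )


def _check_points(points: np.ndarray, name: str) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 3:
        raise GeometryError(f"{name}: need at least 3 points of dimension 3")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError(f"{name}: points are collinear or coincident")
    return points


def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1) such that ``rotation @ mobile_i + translation`` best fits
    ``target_i`` in the least-squares sense (Kabsch alignment).
    """
    mobile = _check_points(mobile, "mobile")
    target = _check_points(target, "target")
    if mobile.shape != target.shape:
        raise GeometryError("point sets differ in size")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - R @ mc
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return R, t, rmsd


def install_conformation(
    scaffold: Scaffold,
    conf: PeptideConformation,
    reference_pocket: np.ndarray | None = None,
    keep_existing: bool = True,
) -> Scaffold:
    """Add a peptide conformation to a scaffold via pocket superposition.

    The conformation's source pocket frame (its own complex's pocket Cα
    coordinates, paired point-for-point with the scaffold's pocket) is
    superposed onto the scaffold pocket and the same rigid motion is
    applied to the peptide backbone.  Chains A/B are never touched.
    """
    pocket = conf.source_pocket if reference_pocket is None else np.asarray(reference_pocket)
    if pocket is None:
        raise GeometryError("conformation carries no source pocket frame")
    target = scaffold.pocket_coords()
    if pocket.shape != target.shape:
        raise GeometryError(
            f"pocket frame mismatch: source {pocket.shape} vs scaffold {target.shape}"
        )
    R, t, _ = superpose(pocket, target)
    moved = replace(
        conf,
        ca=conf.ca @ R.T + t,
        cb=conf.cb @ R.T + t,
        source_pocket=pocket @ R.T + t,
    )
    conformations = list(scaffold.conformations) if keep_existing else []
    conformations.append(moved)
    return replace(scaffold, conformations=conformations)


def read_sidecar(path: str | Path) -> dict[str, str]:
    """Parse a ``key value`` sidecar metadata file (one entry per line)."""
    meta: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(" ")
        meta[key] = value.strip()
    return meta


def _parse_pocket(spec: str) -> list[tuple[str, int]]:
    out = []
    for token in spec.replace(",", " ").split():
        chain, _, idx = token.partition(":")
        out.append((chain, int(idx)))
    if not out:
        raise InputError("empty pocket residue list")
    return out


def load_scaffold(pdb_path: str | Path) -> Scaffold:
    """Load one scaffold PDB (+ sidecar) with its own chain-P conformation."""
    pdb_path = Path(pdb_path)
    meta_path = pdb_path.with_suffix(".meta")
    if not meta_path.exists():
        raise InputError(f"missing sidecar metadata {meta_path}")
    meta = read_sidecar(meta_path)
    model = parse_pdb(pdb_path.read_text(), source_id=pdb_path.stem, build_virtual_cb=True)
    if "P" not in model.chains:
        raise InputError(f"{pdb_path}: scaffold file lacks peptide chain P")
    pocket = _parse_pocket(meta["pocket"])
    peptide = model.chains["P"]
    length = len(peptide)
    core_start = int(meta.get("core_start", (length - CORE_LENGTH) // 2))
    scaffold = Scaffold(
        allele=meta.get("allele", ""),
        model=model.subset(["A", "B"]),
        conformations=[],
        pocket_residues=pocket,
        meta_score=float(meta.get("meta_score", 0.0)),
        source_id=pdb_path.stem,
    )
    conf = PeptideConformation(
        length=length,
        ca=np.array([r.ca for r in peptide]),
        cb=np.array([r.cb if r.cb is not None else r.ca for r in peptide]),
        core_start=core_start,
        source_id=pdb_path.stem,
        source_pocket=scaffold.pocket_coords(),
    )
    scaffold.conformations.append(conf)
    return scaffold


def load_scaffold_set(
    paths: Sequence[str | Path],
    allele: str | None = None,
    top_n_models: int = 2,
    conformations_per_model: int = 5,
) -> list[Scaffold]:
    """Select the top-scoring scaffold models and populate their conformations.

    Models are ranked by meta-score (descending; ties broken by source
    id).  The chain-P conformations of *all* input files form a shared
    pool, ranked the same way; each selected model receives the first
    ``conformations_per_model`` pool entries, installed into its frame
    by pocket superposition.
    """
    loaded = [load_scaffold(p) for p in paths]
    if allele is not None:
        loaded = [s for s in loaded if s.allele == allele]
        if not loaded:
            raise InputError(f"no scaffolds for allele {allele!r}")
    loaded.sort(key=lambda s: (-s.meta_score, s.source_id))
    if len(loaded) < top_n_models:
        logger.warning(
            "requested %d models but only %d available; using all", top_n_models, len(loaded)
        )
    selected = loaded[: min(top_n_models, len(loaded))]
    pool = [s.conformations[0] for s in loaded]
    if len(pool) < conformations_per_model:
        logger.warning(
            "requested %d conformations but only %d available; using all",
            conformations_per_model, len(pool),
        )
    pool = pool[: min(conformations_per_model, len(pool))]
    out = []
    for s in selected:
        bare = replace(s, conformations=[])
        for conf in pool:
            bare = install_conformation(bare, conf)
        out.append(bare)
    return out
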