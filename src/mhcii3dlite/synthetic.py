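"""Synthetic fixtures: planted potentials, toy scaffolds, peptide sets.

Everything the prediction pipeline consumes can be generated here
without downloads: pair-distance observations whose density ratios
encode known ("planted") energies, idealized scaffold geometries with a
groove and a peptide placeholder, labelled binder/non-binder peptide
sets whose binders carry groove-complementary residues in the core, and
(rank, IC50) calibration pairs from a known linear model.

Geometry is deliberately idealized — extended strands with fixed 3.8 Å
Cα spacing and a constant groove separation — because the scoring
machinery only ever sees distances; planted distance preferences
exercise every code path that real structures would.

All generators are driven by an explicit integer seed and are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .pdbio import (
    AMINO_ACIDS,
    PairObservation,
    ResidueRecord,
    StructureModel,
    _canonical,
    write_pdb,
)
from .rankic50 import IC50Model
from .scaffold import CORE_LENGTH, PEPTIDE_LENGTHS, PeptideConformation, Scaffold
from .ssf import CANONICAL_PAIRS, SSFConfig

#: ideal extended-strand Cα spacing, Å
CA_SPACING = 3.8
#: default peptide-groove strand separation, Å (inside the 4-6 Å contact band)
GROOVE_DISTANCE = 5.0


@dataclass
class PlantedPotential:
    """Known pair-energy preferences to plant into generated observations.

    ``favored_pairs`` maps a canonical amino-acid pair to distance bands
    with target energies; within a band the pair's density is
    exp(-E/kT) times the uniform background density, so Boltzmann
    inversion must recover E.  All other pairs are drawn from the
    uniform background on (0, cutoff).
    """

    favored_pairs: dict[tuple[str, str], list[tuple[float, float, float]]] = field(
        default_factory=dict
    )
    atom_type: str = "CA"
    contact_class: str = "inter_chain"
    cutoff: float = 15.0
    kT: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        normalized = {}
        for pair, bands in self.favored_pairs.items():
            for lo, hi, e in bands:
                if not (0 <= lo < hi <= self.cutoff):
                    raise ParameterError(f"band [{lo}, {hi}) outside (0, {self.cutoff}]")
                if not np.isfinite(e):
                    raise ParameterError("planted energy must be finite")
            normalized[_canonical(*pair)] = list(bands)
        self.favored_pairs = normalized

    def density_ratio(self, pair: tuple[str, str], distance: float) -> float:
        """Planted density ratio to the background at a distance."""
        for lo, hi, e in self.favored_pairs.get(_canonical(*pair), []):
            if lo <= distance < hi:
                return float(np.exp(-e / self.kT))
        return 1.0

    def bin_densities(self, pair: tuple[str, str], config: SSFConfig) -> np.ndarray:
        """Exact normalised per-bin probability mass of a pair's distances."""
        edges = config.bin_edges
        mids = (edges[:-1] + edges[1:]) / 2.0
        rel = np.array([self.density_ratio(pair, m) for m in mids]) * config.bin_width
        return rel / rel.sum()

    def expected_energies(
        self,
        pair: tuple[str, str],
        pair_set: Sequence[tuple[str, str]],
        config: SSFConfig,
        n_per_pair: int | None = None,
    ) -> np.ndarray:
        """Closed-form expected compiled energy per bin for a pair.

        Accounts for the two systematic effects the histogram path is
        subject to: band normalisation of the pair's own density, and
        contamination of the pooled reference state by the planted
        pairs (all pairs contribute equal observation counts).  With
        ``n_per_pair`` given, pseudocount shrinkage toward the
        reference is included as well.  This is an independent oracle:
        it never touches observation sampling or histogramming.
        """
        pair = _canonical(*pair)
        f_ab = self.bin_densities(pair, config)
        f_ref = np.mean(
            [self.bin_densities(_canonical(*p), config) for p in pair_set], axis=0
        )
        if n_per_pair is not None:
            m = config.pseudocount_weight
            f_ab = (n_per_pair * f_ab + m * f_ref) / (n_per_pair + m)
        return -config.kT * np.log(f_ab / f_ref)


@dataclass
class SyntheticSpec:
    """Study-condition knobs for generated peptide/calibration sets."""

    n_observations: int = 50_000
    n_peptides: int = 400
    peptide_length: int = 15
    binder_fraction: float = 0.5
    noise_sigma: float = 0.05
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_observations < 1 or self.n_peptides < 1:
            raise ParameterError("counts must be >= 1")
        if self.peptide_length not in PEPTIDE_LENGTHS:
            raise ParameterError(f"peptide_length must be one of {PEPTIDE_LENGTHS}")
        if not 0.0 <= self.binder_fraction <= 1.0:
            raise ParameterError("binder_fraction must be in [0, 1]")


def _sample_pair_distances(
    planted: PlantedPotential,
    pair: tuple[str, str],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample distances from the piecewise-constant planted density."""
    bands = planted.favored_pairs.get(pair, [])
    if not bands:
        return rng.uniform(0.0, planted.cutoff, n)
    # split (0, cutoff) into segments with constant relative density
    edges = sorted({0.0, planted.cutoff} | {b for lo, hi, _ in bands for b in (lo, hi)})
    segments = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = (lo + hi) / 2.0
        segments.append((lo, hi, planted.density_ratio(pair, mid)))
    weights = np.array([(hi - lo) * ratio for lo, hi, ratio in segments])
    weights /= weights.sum()
    counts = rng.multinomial(n, weights)
    chunks = [
        rng.uniform(lo, hi, c) for (lo, hi, _), c in zip(segments, counts) if c > 0
    ]
    out = np.concatenate(chunks) if chunks else np.empty(0)
    rng.shuffle(out)
    return out


def gen_observations(
    planted: PlantedPotential,
    n_per_pair: int,
    pairs: Sequence[tuple[str, str]] | None = None,
    atom_type: str | None = None,
    contact_class: str | None = None,
) -> list[PairObservation]:
    """Generate ``n_per_pair`` distance observations for each pair.

    Favored pairs follow the planted density; everything else is the
    uniform background.  Defaults to all 210 canonical pairs.
    """
    if n_per_pair < 1:
        raise ParameterError("n_per_pair must be >= 1")
    rng = np.random.default_rng(planted.seed)
    at = atom_type or planted.atom_type
    cc = contact_class or planted.contact_class
    pair_list = [_canonical(*p) for p in (pairs or CANONICAL_PAIRS)]
    observations: list[PairObservation] = []
    for pair in pair_list:
        distances = _sample_pair_distances(planted, pair, n_per_pair, rng)
        distances = distances[distances > 0]
        observations.extend(
            PairObservation(pair[0], pair[1], at, cc, float(d)) for d in distances
        )
    return observations


def _strand_model(
    groove_a: str, groove_b: str, peptide_length: int,
    contact_distance: float, jitter_sigma: float, rng: np.random.Generator,
    source_id: str,
) -> StructureModel:
    def records(chain_id: str, seq: str, z: float) -> list[ResidueRecord]:
        out = []
        for i, aa in enumerate(seq):
            base = np.array([CA_SPACING * i, 0.0, z])
            jitter = rng.normal(0.0, jitter_sigma, 3) if jitter_sigma > 0 else 0.0
            ca = base + jitter
            cb = ca + np.array([0.0, 1.53, 0.0])
            out.append(ResidueRecord(chain_id, i + 1, aa, ca, cb))
        return out

    placeholder = "A" * peptide_length  # alanine placeholder peptide
    return StructureModel(
        chains={
            "A": records("A", groove_a, +contact_distance),
            "B": records("B", groove_b, -contact_distance),
            "P": records("P", placeholder, 0.0),
        },
        source_id=source_id,
    )


def gen_toy_scaffold(
    groove_residues: tuple[str, str],
    peptide_length: int = 15,
    seed: int = 0,
    contact_distance: float = GROOVE_DISTANCE,
    jitter_sigma: float = 0.0,
    core_start: int | None = None,
    allele: str = "TOY*01:01",
    source_id: str = "toy01",
    meta_score: float = 1.0,
    out_dir: str | Path | None = None,
) -> Scaffold:
    """Build an idealized groove + placeholder-peptide scaffold.

    Chain P is an extended strand (3.8 Å Cα spacing) flanked by two
    parallel groove strands (chains A and B) at ``contact_distance``, so
    every core position has at least one inter-chain contact well inside
    the potential cutoff.  With ``out_dir`` set, writes the PDB fixture
    plus its ``.meta`` sidecar and the scaffold can be reloaded from disk.
    """
    groove_a, groove_b = groove_residues
    if peptide_length not in PEPTIDE_LENGTHS:
        raise ParameterError(f"peptide_length must be one of {PEPTIDE_LENGTHS}")
    if len(groove_a) != peptide_length or len(groove_b) != peptide_length:
        raise ParameterError("groove strings must match peptide_length")
    rng = np.random.default_rng(seed)
    model = _strand_model(
        groove_a, groove_b, peptide_length, contact_distance, jitter_sigma, rng, source_id
    )
    if core_start is None:
        core_start = (peptide_length - CORE_LENGTH) // 2
    core = range(core_start + 1, core_start + CORE_LENGTH + 1)  # 1-based indices
    pocket = [("A", i) for i in core] + [("B", i) for i in core]
    peptide = model.chains["P"]
    scaffold = Scaffold(
        allele=allele,
        model=model.subset(["A", "B"]),
        conformations=[],
        pocket_residues=pocket,
        meta_score=meta_score,
        source_id=source_id,
    )
    conf = PeptideConformation(
        length=peptide_length,
        ca=np.array([r.ca for r in peptide]),
        cb=np.array([r.cb for r in peptide]),
        core_start=core_start,
        source_id=source_id,
        source_pocket=scaffold.pocket_coords(),
    )
    scaffold.conformations.append(conf)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{source_id}.pdb").write_text(write_pdb(model))
        (out_dir / f"{source_id}.meta").write_text(
            f"allele {allele}\nmeta_score {meta_score!r}\n"
            f"core_start {core_start}\n"
            "pocket " + " ".join(f"{c}:{i}" for c, i in pocket) + "\n"
        )
    return scaffold


def _binder_core_aa(planted: PlantedPotential, scaffold: Scaffold) -> str:
    """Residue whose planted partner sits in the groove of the scaffold."""
    groove_letters = {
        r.aa for cid in ("A", "B") for r in scaffold.model.chains[cid]
    }
    for (a, b), bands in planted.favored_pairs.items():
        if not any(e < 0 for _, _, e in bands):
            continue
        if a in groove_letters:
            return b
        if b in groove_letters:
            return a
    raise ParameterError("no favorable planted pair matches the groove residues")


def gen_peptides(
    spec: SyntheticSpec,
    planted: PlantedPotential,
    groove: Scaffold,
) -> pd.DataFrame:
    """Labelled peptide set: binders carry groove-complementary cores.

    Binders are random peptides whose centered 9-mer core is filled with
    the residue favored (negative planted energy) against the groove
    residues; non-binders are uniform random.  Returns a DataFrame with
    columns ``peptide`` and ``label`` (1 = binder).
    """
    rng = np.random.default_rng(spec.seed)
    binder_aa = _binder_core_aa(planted, groove)
    n_binders = int(round(spec.n_peptides * spec.binder_fraction))
    core_start = (spec.peptide_length - CORE_LENGTH) // 2
    letters = np.array(list(AMINO_ACIDS))
    rows = []
    for k in range(spec.n_peptides):
        seq = list(rng.choice(letters, spec.peptide_length))
        label = 1 if k < n_binders else 0
        if label:
            seq[core_start:core_start + CORE_LENGTH] = [binder_aa] * CORE_LENGTH
        rows.append(("".join(seq), label))
    return pd.DataFrame(rows, columns=["peptide", "label"])


def gen_background_peptides(n: int, length: int = 15, seed: int = 0) -> list[str]:
    """Uniform random background peptides (proxy for a non-redundant sample)."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    return ["".join(rng.choice(letters, length)) for _ in range(n)]


def gen_rank_ic50(
    model: IC50Model, n: int, noise_sigma: float = 0.0, seed: int = 0
) -> np.ndarray:
    """(rank, IC50) calibration pairs from a known linear model plus noise.

    Ranks are uniform on [0, 1]; transformed affinities get Gaussian
    noise and are back-converted to IC50, capped at the saturation.
    Returns an (n, 2) array of (rank, ic50).
    """
    rng = np.random.default_rng(seed)
    ranks = rng.uniform(0.0, 1.0, n)
    y = model.slope * ranks + model.intercept
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, n)
    ic50 = model.saturation ** (1.0 - y)
    ic50 = np.minimum(ic50, model.saturation)
    return np.column_stack([ranks, ic50])
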