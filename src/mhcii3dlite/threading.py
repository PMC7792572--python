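"""Thread antigen sequences through scaffold conformations and score them.

For every (model, conformation) combination the antigen sequence is slid
along the peptide backbone.  A placement assigns a contiguous stretch of
the sequence to conformation positions such that the 9-mer core is fully
occupied; flank positions that fall outside the sequence stay empty and
contribute nothing.  Each placement's net energy dE(S, C) is the sum of
pair-potential terms over

* peptide-MHC residue pairs (inter-chain potential), and
* peptide-internal residue pairs (intra-chain potential, sequence
  separation >= k_min),

evaluated at the scaffold's fixed backbone distances for every enabled
atom type.  Per combination the best (lowest-energy) placement is kept
and the binding score is the arithmetic mean over combinations.  Lower
scores mean better predicted binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import AlleleLookupError, InputError
from .pdbio import AA_INDEX
from .scaffold import CORE_LENGTH, PeptideConformation, Scaffold
from .ssf import PairSSF

#: default minimal sequence separation for peptide-internal pairs
K_MIN = 2


@dataclass
class Placement:
    """One threading window of the antigen on one (model, conformation)."""

    window_start: int
    model_id: str
    conformation_id: str
    occupancy: dict[int, int]  # conformation position -> sequence position
    energy: float


@dataclass
class ThreadResult:
    """Best placement per combination and their mean binding score."""

    placements: dict[tuple[str, str], Placement]
    binding_score: float
    n_windows: int


@dataclass
class PredictionRecord:
    """Final per-peptide prediction."""

    allele: str
    peptide: str
    window_start: int
    score: float
    rank: float
    ic50_pred: float
    binder_class: str


class _ConformationContacts:
    """Precomputed contact lists of one positioned conformation.

    Distances never change during threading (rigid scaffold), so for
    each conformation position we cache the partner amino-acid indices,
    atom-type/contact-class energy tables and bin indices once, turning
    placement scoring into table lookups.
    """

    def __init__(self, scaffold: Scaffold, conf: PeptideConformation, ssf: PairSSF,
                 k_min: int = K_MIN):
        cfg = ssf.config
        self.length = conf.length
        self.core_start = conf.core_start
        mhc_aa = []
        mhc_ca = []
        mhc_cb = []
        for cid in ("A", "B"):
            for r in scaffold.model.chains[cid]:
                mhc_aa.append(AA_INDEX[r.aa])
                mhc_ca.append(r.ca)
                mhc_cb.append(r.cb if r.cb is not None else r.ca)
        mhc_aa = np.array(mhc_aa)
        pep_xyz = {"CA": conf.ca, "CB": conf.cb}
        mhc_xyz = {"CA": np.array(mhc_ca), "CB": np.array(mhc_cb)}
        # inter-chain: conformation position x MHC residue
        pos_l, partner_l, table_l, bin_l = [], [], [], []
        self._tables: list[np.ndarray] = []
        for at in cfg.atom_types:
            if "inter_chain" not in cfg.contact_classes:
                break
            table_id = len(self._tables)
            self._tables.append(ssf.energy_table(at, "inter_chain"))
            d = np.linalg.norm(
                pep_xyz[at][:, None, :] - mhc_xyz[at][None, :, :], axis=2
            )
            ii, jj = np.nonzero(d < cfg.cutoff)
            bins = (d[ii, jj] // cfg.bin_width).astype(int)
            pos_l.append(ii)
            partner_l.append(mhc_aa[jj])
            table_l.append(np.full(len(ii), table_id))
            bin_l.append(bins)
        self.inter_pos = np.concatenate(pos_l) if pos_l else np.empty(0, int)
        self.inter_partner = np.concatenate(partner_l) if partner_l else np.empty(0, int)
        self.inter_table = np.concatenate(table_l) if table_l else np.empty(0, int)
        self.inter_bin = np.concatenate(bin_l) if bin_l else np.empty(0, int)
        # peptide-internal: position pairs with separation >= k_min
        pi_l, pj_l, ptable_l, pbin_l = [], [], [], []
        for at in cfg.atom_types:
            if "intra_chain" not in cfg.contact_classes:
                break
            table_id = len(self._tables)
            self._tables.append(ssf.energy_table(at, "intra_chain"))
            xyz = pep_xyz[at]
            d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
            ii, jj = np.nonzero(d < cfg.cutoff)
            keep = (jj - ii) >= k_min
            ii, jj = ii[keep], jj[keep]
            pi_l.append(ii)
            pj_l.append(jj)
            ptable_l.append(np.full(len(ii), table_id))
            pbin_l.append((d[ii, jj] // cfg.bin_width).astype(int))
        self.intra_i = np.concatenate(pi_l) if pi_l else np.empty(0, int)
        self.intra_j = np.concatenate(pj_l) if pj_l else np.empty(0, int)
        self.intra_table = np.concatenate(ptable_l) if ptable_l else np.empty(0, int)
        self.intra_bin = np.concatenate(pbin_l) if pbin_l else np.empty(0, int)
        self.table_stack = (
            np.stack(self._tables) if self._tables
            else np.zeros((1, 20, 20, ssf.config.n_bins))
        )

    def score_occupancy(self, occ: np.ndarray) -> float:
        """Energy of one placement; ``occ[p]`` = aa index at position p, -1 empty."""
        e = 0.0
        if len(self.inter_pos):
            aa = occ[self.inter_pos]
            mask = aa >= 0
            if mask.any():
                e += self.table_stack[
                    self.inter_table[mask], aa[mask], self.inter_partner[mask],
                    self.inter_bin[mask],
                ].sum()
        if len(self.intra_i):
            ai = occ[self.intra_i]
            aj = occ[self.intra_j]
            mask = (ai >= 0) & (aj >= 0)
            if mask.any():
                e += self.table_stack[
                    self.intra_table[mask], ai[mask], aj[mask], self.intra_bin[mask]
                ].sum()
        return float(e)


def _seq_to_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in sequence.upper()])
    except KeyError as exc:
        raise InputError(f"unknown amino-acid letter {exc.args[0]!r}") from exc


def enumerate_offsets(length: int, core_start: int, n: int) -> range:
    """Alignment offsets t (conformation position p holds sequence p + t)
    for which the 9-mer core is fully inside the sequence."""
    return range(-core_start, n - CORE_LENGTH - core_start + 1)


def score_placement(
    scaffold: Scaffold,
    conf_index: int,
    window: str,
    offset_in_conf: int,
    ssf: PairSSF,
    k_min: int = K_MIN,
) -> float:
    """Score one explicit placement of ``window`` starting at a conformation position.

    ``offset_in_conf`` is the conformation position occupied by the first
    window residue; the placement must cover the 9-mer core.
    """
    conf = scaffold.conformations[conf_index]
    occ = np.full(conf.length, -1)
    w = _seq_to_indices(window)
    end = offset_in_conf + len(w)
    if offset_in_conf < 0 or end > conf.length:
        raise InputError("window does not fit in the conformation")
    occ[offset_in_conf:end] = w
    core = range(conf.core_start, conf.core_start + CORE_LENGTH)
    if any(occ[p] < 0 for p in core):
        raise InputError("placement does not cover the 9-mer core")
    contacts = _ConformationContacts(scaffold, conf, ssf, k_min)
    return contacts.score_occupancy(occ)


def thread_sequence(
    antigen: str,
    scaffolds: Sequence[Scaffold],
    ssf: PairSSF,
    k_min: int = K_MIN,
    _contacts_cache: dict | None = None,
) -> ThreadResult:
    """Slide ``antigen`` through every (model, conformation) combination.

    Keeps the lowest-energy placement per combination (ties resolved
    toward the smallest window start) and averages them into the binding
    score.
    """
    if len(antigen) < CORE_LENGTH:
        raise InputError(f"antigen shorter than the {CORE_LENGTH}-mer core")
    seq = _seq_to_indices(antigen)
    n = len(seq)
    placements: dict[tuple[str, str], Placement] = {}
    n_windows = 0
    for scaffold in scaffolds:
        for ci, conf in enumerate(scaffold.conformations):
            key = (scaffold.source_id, conf.source_id or str(ci))
            cache_key = (id(scaffold), ci)
            if _contacts_cache is not None and cache_key in _contacts_cache:
                contacts = _contacts_cache[cache_key]
            else:
                contacts = _ConformationContacts(scaffold, conf, ssf, k_min)
                if _contacts_cache is not None:
                    _contacts_cache[cache_key] = contacts
            best: Placement | None = None
            for t in enumerate_offsets(conf.length, conf.core_start, n):
                occ = np.full(conf.length, -1)
                p = np.arange(conf.length)
                s = p + t
                valid = (s >= 0) & (s < n)
                occ[valid] = seq[s[valid]]
                energy = contacts.score_occupancy(occ)
                n_windows += 1
                window_start = max(t, 0)
                if best is None or energy < best.energy or (
                    energy == best.energy and window_start < best.window_start
                ):
                    best = Placement(
                        window_start=window_start,
                        model_id=key[0],
                        conformation_id=key[1],
                        occupancy={int(p_): int(p_ + t) for p_ in p[valid]},
                        energy=energy,
                    )
            placements[key] = best
    if not placements:
        raise InputError("no scaffold conformations to thread through")
    score = float(np.mean([p.energy for p in placements.values()]))
    return ThreadResult(placements=placements, binding_score=score, n_windows=n_windows)


def background_scores(
    peptides: Iterable[str],
    scaffolds: Sequence[Scaffold],
    ssf: PairSSF,
    k_min: int = K_MIN,
) -> np.ndarray:
    """Binding scores of a background peptide set (shared contact cache)."""
    cache: dict = {}
    return np.array(
        [thread_sequence(p, scaffolds, ssf, k_min, _contacts_cache=cache).binding_score
         for p in peptides]
    )


def predict(
    antigen: str,
    allele: str,
    scaffold_store: Mapping[str, Sequence[Scaffold]],
    ssf: PairSSF,
    background: np.ndarray,
    ic50_model,
    cutoff_nm: float = 500.0,
    k_min: int = K_MIN,
    _contacts_cache: dict | None = None,
) -> PredictionRecord:
    """Full pipeline for one peptide: thread, rank, map to IC50, classify."""
    from .rankic50 import binding_rank, classify, predict_ic50

    if allele not in scaffold_store:
        raise AlleleLookupError(
            f"no scaffolds for allele {allele!r}; available: {sorted(scaffold_store)}"
        )
    result = thread_sequence(antigen, scaffold_store[allele], ssf, k_min,
                             _contacts_cache=_contacts_cache)
    rank = binding_rank(result.binding_score, background)
    ic50 = predict_ic50(ic50_model, rank)
    best = min(result.placements.values(), key=lambda p: p.energy)
    return PredictionRecord(
        allele=allele,
        peptide=antigen,
        window_start=best.window_start,
        score=result.binding_score,
        rank=rank,
        ic50_pred=ic50,
        binder_class=classify(ic50, cutoff_nm),
    )
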