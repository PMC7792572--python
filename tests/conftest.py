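"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's vectorised code paths
(contact tables, histogram pipelines): they recompute energies pair by
pair via ``PairSSF.energy`` and Python loops, so agreement is a real
cross-check and not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from mhcii3dlite import synthetic as syn
from mhcii3dlite.pdbio import AMINO_ACIDS
from mhcii3dlite.scaffold import CORE_LENGTH, Scaffold
from mhcii3dlite.ssf import CANONICAL_PAIRS, PairSSF, SSFConfig, DistanceHistogram


def make_ssf(
    planted_energies: dict | None = None,
    config: SSFConfig | None = None,
    rng: np.random.Generator | None = None,
    random_scale: float = 0.0,
) -> PairSSF:
    """Directly construct a PairSSF with chosen (or random) bin energies.

    ``planted_energies`` maps (atom_type, contact_class, (a, b)) to either a
    full per-bin array or a {bin_index: energy} dict.
    """
    config = config or SSFConfig()
    energies = {}
    reference = {}
    for at in config.atom_types:
        for cc in config.contact_classes:
            reference[(at, cc)] = DistanceHistogram(
                config.bin_edges, np.ones(config.n_bins)
            )
            for pair in CANONICAL_PAIRS:
                if random_scale > 0 and rng is not None:
                    e = rng.normal(0.0, random_scale, config.n_bins)
                else:
                    e = np.zeros(config.n_bins)
                energies[(at, cc, pair)] = e
    for key, value in (planted_energies or {}).items():
        at, cc, pair = key
        pair = tuple(sorted(pair))
        if isinstance(value, dict):
            for b, e in value.items():
                energies[(at, cc, pair)][b] = e
        else:
            energies[(at, cc, pair)] = np.asarray(value, dtype=float)
    return PairSSF(config, energies, reference)


def naive_thread(antigen: str, scaffold: Scaffold, ssf: PairSSF, k_min: int = 2):
    """Exhaustive window enumeration, scored residue pair by residue pair.

    Returns {conformation_index: (best_energy, window_start)} plus the mean.
    """
    cfg = ssf.config
    mhc = [r for cid in ("A", "B") for r in scaffold.model.chains[cid]]
    results = {}
    for ci, conf in enumerate(scaffold.conformations):
        n = len(antigen)
        best = None
        for t in range(-conf.core_start, n - CORE_LENGTH - conf.core_start + 1):
            occupied = {p: t + p for p in range(conf.length) if 0 <= t + p < n}
            energy = 0.0
            for p, s in occupied.items():
                aa_p = antigen[s]
                for at in cfg.atom_types:
                    if "inter_chain" not in cfg.contact_classes:
                        continue
                    xyz_p = conf.ca[p] if at == "CA" else conf.cb[p]
                    for r in mhc:
                        xyz_r = r.ca if at == "CA" else (r.cb if r.cb is not None else r.ca)
                        d = float(np.linalg.norm(xyz_p - xyz_r))
                        energy += ssf.energy(aa_p, r.aa, at, "inter_chain", d)
            if "intra_chain" in cfg.contact_classes:
                for p, s in occupied.items():
                    for q, u in occupied.items():
                        if q - p < k_min:
                            continue
                        for at in cfg.atom_types:
                            xp = conf.ca[p] if at == "CA" else conf.cb[p]
                            xq = conf.ca[q] if at == "CA" else conf.cb[q]
                            d = float(np.linalg.norm(xp - xq))
                            energy += ssf.energy(antigen[s], antigen[u], at, "intra_chain", d)
            start = max(t, 0)
            if best is None or energy < best[0] or (energy == best[0] and start < best[1]):
                best = (energy, start)
        results[ci] = best
    mean = float(np.mean([b[0] for b in results.values()]))
    return results, mean


def random_toy_instance(seed: int):
    """A random (sequence, scaffold, ssf) triple for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    length = int(rng.choice([9, 11, 13, 15]))
    letters = list(AMINO_ACIDS)
    groove_a = "".join(rng.choice(letters, length))
    groove_b = "".join(rng.choice(letters, length))
    scaffold = syn.gen_toy_scaffold(
        (groove_a, groove_b), peptide_length=length, seed=seed,
        jitter_sigma=0.05, source_id=f"rand{seed}",
    )
    n = int(rng.integers(9, 61))
    antigen = "".join(rng.choice(letters, n))
    ssf = make_ssf(rng=rng, random_scale=0.5)
    return antigen, scaffold, ssf


@pytest.fixture(scope="session")
def planted_wide() -> syn.PlantedPotential:
    """Default discrimination study condition: (F,L) favored in [4,10) A."""
    return syn.PlantedPotential(
        favored_pairs={("F", "L"): [(4.0, 10.0, -np.log(2.0))]}, seed=1
    )


@pytest.fixture(scope="session")
def toy_scaffold() -> Scaffold:
    return syn.gen_toy_scaffold(("L" * 15, "L" * 15))


@pytest.fixture(scope="session")
def compiled_planted_ssf(planted_wide):
    """SSF compiled from sampled observations of the planted potential.

    Inter-chain CA carries the planted signal; the other three channels
    are compiled from null (uniform) observations.
    """
    from mhcii3dlite.ssf import compile_ssf

    pairs = sorted(set(CANONICAL_PAIRS[:40]) | {("F", "L")})
    obs = syn.gen_observations(planted_wide, 5000, pairs=pairs)
    for at, cc in (("CA", "intra_chain"), ("CB", "inter_chain"), ("CB", "intra_chain")):
        null = syn.PlantedPotential(seed=2, atom_type=at, contact_class=cc)
        obs += syn.gen_observations(null, 2000, pairs=pairs)
    return compile_ssf(obs, provenance="planted toy potential")
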