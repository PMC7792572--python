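"""Distance-dependent residue-pair statistical scoring functions.

A pair potential is obtained by Boltzmann inversion of observed
distance distributions:

    dE_ab(r) = -kT * ln( f_ab(r) / f(r) )

where ``f_ab`` is the distance distribution of amino-acid pair (a, b)
and the reference state ``f`` pools all pairs of the same atom type and
contact class.  Distances enter fixed-width half-open bins [lo, hi) up
to a cutoff; beyond the cutoff pairs are treated as non-interacting
(energy 0).  Sparse pairs are smoothed toward the reference state with
a pseudocount weight m:

    f~_ab = (n_ab * f_ab + m * f) / (n_ab + m)

so rare pairs get finite energies that shrink to 0 as data vanish.

Potentials are kept separately per atom type (Cα–Cα, Cβ–Cβ) and per
contact class (inter-chain vs intra-chain), reflecting that interface
contacts and within-chain contacts have different distance statistics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import CompileError, ParameterError, PotentialFormatError
from .pdbio import AMINO_ACIDS, ATOM_TYPES, CONTACT_CLASSES, PairObservation, _canonical

FORMAT_VERSION = 1

CANONICAL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    combinations_with_replacement(AMINO_ACIDS, 2)
)
PAIR_INDEX = {p: i for i, p in enumerate(CANONICAL_PAIRS)}


@dataclass(frozen=True)
class SSFConfig:
    """Binning and smoothing parameters of a pair potential."""

    bin_width: float = 1.0
    cutoff: float = 15.0
    kT: float = 1.0
    pseudocount_weight: float = 50.0
    contact_classes: tuple[str, ...] = CONTACT_CLASSES
    atom_types: tuple[str, ...] = ATOM_TYPES

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        if self.kT <= 0:
            raise ParameterError("kT must be positive")
        if self.pseudocount_weight < 0:
            raise ParameterError("pseudocount_weight must be non-negative")
        n = self.cutoff / self.bin_width
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ParameterError("cutoff must be a positive integer multiple of bin_width")
        for cc in self.contact_classes:
            if cc not in CONTACT_CLASSES:
                raise ParameterError(f"unknown contact class {cc!r}")
        for at in self.atom_types:
            if at not in ATOM_TYPES:
                raise ParameterError(f"unknown atom type {at!r}")

    @property
    def n_bins(self) -> int:
        return int(round(self.cutoff / self.bin_width))

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    def bin_of(self, distance: float) -> int | None:
        """Half-open bin index of a distance, or None beyond the cutoff."""
        if distance < 0:
            raise ParameterError("distance must be non-negative")
        if distance >= self.cutoff:
            return None
        return min(int(distance // self.bin_width), self.n_bins - 1)


@dataclass
class DistanceHistogram:
    """Raw per-bin counts over the configured bin edges."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ParameterError("counts/bin_edges length mismatch")
        if np.any(self.counts < 0):
            raise ParameterError("negative counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def density(self) -> np.ndarray:
        """Normalised per-bin probability mass (uniform if empty)."""
        t = self.total
        if t == 0:
            return np.full(len(self.counts), 1.0 / len(self.counts))
        return self.counts / t


@dataclass
class PairSSF:
    """Compiled pair potential: per-bin energies for every canonical pair."""

    config: SSFConfig
    energies: dict[tuple[str, str, tuple[str, str]], np.ndarray]
    reference: dict[tuple[str, str], DistanceHistogram]
    pair_counts: dict[tuple[str, str, tuple[str, str]], float] = field(default_factory=dict)
    provenance: str = ""

    def energy(
        self, aa_a: str, aa_b: str, atom_type: str, contact_class: str, distance: float
    ) -> float:
        """Energy of the bin containing ``distance`` (0 beyond the cutoff)."""
        pair = _canonical(aa_a, aa_b)
        if pair not in PAIR_INDEX:
            raise ParameterError(f"unknown amino-acid pair {aa_a}{aa_b}")
        b = self.config.bin_of(distance)
        if b is None:
            return 0.0
        return float(self.energies[(atom_type, contact_class, pair)][b])

    def energy_table(self, atom_type: str, contact_class: str) -> np.ndarray:
        """Dense (20, 20, n_bins) symmetric lookup table for fast threading."""
        table = np.zeros((20, 20, self.config.n_bins))
        for (a, b), _ in PAIR_INDEX.items():
            e = self.energies[(atom_type, contact_class, (a, b))]
            ia, ib = AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)
            table[ia, ib] = e
            table[ib, ia] = e
        return table


def evaluate_pair(
    ssf: PairSSF, aa_a: str, aa_b: str, atom_type: str, contact_class: str, distance: float
) -> float:
    """Functional alias for :meth:`PairSSF.energy`."""
    return ssf.energy(aa_a, aa_b, atom_type, contact_class, distance)


def compile_ssf(
    observations: Iterable[PairObservation],
    config: SSFConfig | None = None,
    provenance: str = "",
) -> PairSSF:
    """Compile pair potentials from distance observations by Boltzmann inversion.

    For each enabled (atom_type, contact_class) the reference state f(r)
    is the pooled normalised histogram of all observations; each pair's
    histogram is smoothed toward f(r) by the pseudocount weight and
    inverted to energies.  Bins where the reference itself is empty get
    energy 0 (no evidence either way).
    """
    config = config or SSFConfig()
    n_bins = config.n_bins
    edges = config.bin_edges
    enabled = [(at, cc) for at in config.atom_types for cc in config.contact_classes]
    pair_hist = {
        key: np.zeros((len(CANONICAL_PAIRS), n_bins)) for key in enabled
    }
    for obs in observations:
        key = (obs.atom_type, obs.contact_class)
        if key not in pair_hist:
            continue
        if obs.distance <= 0:
            raise ParameterError("non-positive observation distance")
        b = config.bin_of(obs.distance)
        if b is None:
            continue
        pair = _canonical(obs.aa_a, obs.aa_b)
        pair_hist[key][PAIR_INDEX[pair], b] += 1.0

    energies: dict[tuple[str, str, tuple[str, str]], np.ndarray] = {}
    reference: dict[tuple[str, str], DistanceHistogram] = {}
    pair_counts: dict[tuple[str, str, tuple[str, str]], float] = {}
    m = config.pseudocount_weight
    for (at, cc) in enabled:
        hist = pair_hist[(at, cc)]
        total_counts = hist.sum(axis=0)
        total = total_counts.sum()
        if total == 0:
            raise CompileError(f"no observations for atom type {at}, contact class {cc}")
        f_ref = total_counts / total
        reference[(at, cc)] = DistanceHistogram(edges, total_counts)
        nonzero = f_ref > 0
        for pair, ip in PAIR_INDEX.items():
            n_ab = hist[ip].sum()
            f_ab = hist[ip] / n_ab if n_ab > 0 else np.zeros(n_bins)
            if n_ab + m > 0:
                f_smooth = (n_ab * f_ab + m * f_ref) / (n_ab + m)
            else:
                f_smooth = f_ref.copy()
            e = np.zeros(n_bins)
            with np.errstate(divide="ignore"):
                ratio = np.divide(f_smooth, f_ref, out=np.ones(n_bins), where=nonzero)
                e[nonzero] = -config.kT * np.log(ratio[nonzero])
            energies[(at, cc, pair)] = e
            pair_counts[(at, cc, pair)] = float(n_ab)
    return PairSSF(config, energies, reference, pair_counts, provenance)


def _fmt_floats(values: Sequence[float]) -> str:
    return " ".join(repr(float(v)) for v in values)


def _payload_lines(ssf: PairSSF) -> list[str]:
    lines: list[str] = []
    for (at, cc), hist in sorted(ssf.reference.items()):
        lines.append(f"[reference {at} {cc}]")
        lines.append("counts " + _fmt_floats(hist.counts))
    for (at, cc, (a, b)), e in sorted(ssf.energies.items()):
        n_ab = ssf.pair_counts.get((at, cc, (a, b)), 0.0)
        lines.append(f"[pair {at} {cc} {a} {b}]")
        lines.append(f"n {n_ab!r}")
        lines.append("energies " + _fmt_floats(e))
    return lines


def save_ssf(ssf: PairSSF, path: str | Path) -> None:
    """Write a potential to the self-describing plain-text format."""
    cfg = ssf.config
    payload = _payload_lines(ssf)
    checksum = zlib.crc32("\n".join(payload).encode())
    header = [
        "# mhcii3dlite pair statistical scoring function",
        f"format_version {FORMAT_VERSION}",
        f"bin_width {cfg.bin_width!r}",
        f"cutoff {cfg.cutoff!r}",
        f"kT {cfg.kT!r}",
        f"pseudocount_weight {cfg.pseudocount_weight!r}",
        "atom_types " + ",".join(cfg.atom_types),
        "contact_classes " + ",".join(cfg.contact_classes),
        "provenance " + ssf.provenance.replace("\n", " "),
        f"checksum {checksum}",
    ]
    Path(path).write_text("\n".join(header + payload) + "\n")


def load_ssf(path: str | Path) -> PairSSF:
    """Load a potential saved by :func:`save_ssf`, verifying version and checksum."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    i = 0
    while i < len(lines) and not lines[i].startswith("["):
        line = lines[i]
        i += 1
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(" ")
        header[key] = value
    if header.get("format_version") != str(FORMAT_VERSION):
        raise PotentialFormatError(
            f"unsupported format_version {header.get('format_version')!r}"
        )
    payload = lines[i:]
    checksum = zlib.crc32("\n".join(payload).encode())
    if str(checksum) != header.get("checksum"):
        raise PotentialFormatError("checksum mismatch: file corrupted")
    config = SSFConfig(
        bin_width=float(header["bin_width"]),
        cutoff=float(header["cutoff"]),
        kT=float(header["kT"]),
        pseudocount_weight=float(header["pseudocount_weight"]),
        atom_types=tuple(header["atom_types"].split(",")),
        contact_classes=tuple(header["contact_classes"].split(",")),
    )
    edges = config.bin_edges
    energies: dict[tuple[str, str, tuple[str, str]], np.ndarray] = {}
    reference: dict[tuple[str, str], DistanceHistogram] = {}
    pair_counts: dict[tuple[str, str, tuple[str, str]], float] = {}
    current: tuple[str, ...] | None = None
    for line in payload:
        if line.startswith("[reference "):
            current = ("ref",) + tuple(line[1:-1].split()[1:])
        elif line.startswith("[pair "):
            current = ("pair",) + tuple(line[1:-1].split()[1:])
        elif line.startswith("counts ") and current and current[0] == "ref":
            counts = np.array([float(x) for x in line.split()[1:]])
            reference[(current[1], current[2])] = DistanceHistogram(edges, counts)
        elif line.startswith("n ") and current and current[0] == "pair":
            pair_counts[(current[1], current[2], (current[3], current[4]))] = float(
                line.split()[1]
            )
        elif line.startswith("energies ") and current and current[0] == "pair":
            e = np.array([float(x) for x in line.split()[1:]])
            energies[(current[1], current[2], (current[3], current[4]))] = e
    ssf = PairSSF(config, energies, reference, pair_counts, header.get("provenance", ""))
    for at in config.atom_types:
        for cc in config.contact_classes:
            for pair in CANONICAL_PAIRS:
                if (at, cc, pair) not in ssf.energies:
                    raise PotentialFormatError(f"missing pair block {at} {cc} {pair}")
    return ssf
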