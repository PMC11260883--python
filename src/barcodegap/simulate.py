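"""Synthetic COI-like genus alignments with controlled barcode-gap structure.

Sequences evolve on a star phylogeny under the two-rate (Kimura) substitution
process that the distance estimator assumes: one transition rate (kappa *
beta) and two transversion rates (beta each), normalized so branch length is
the expected number of substitutions per site.  A genus root sequence is
drawn uniformly over {A, C, G, T}; each species ancestor evolves from the
root along a branch of length ``inter_depth``; each haplotype evolves from
its species ancestor along a branch of length ``intra_depth``.  Two
conspecific haplotypes are therefore separated by an expected 2*intra_depth
substitutions/site, and two heterospecific sequences by 2*inter_depth +
2*intra_depth.

The generator also reproduces the messy features of real barcode data that
the pipeline must cope with: redundant sampling of haplotypes (so the total
sequence count exceeds the haplotype count), identical haplotypes shared
between nominal species (which destroy local barcoding gaps), and missing
blocks at alignment ends (which exercise trimming and pairwise deletion).

Limitations: the star phylogeny has no within-species coalescent structure
and no rate variation among sites or lineages, so realized distances are
tighter around their expectations than in real genera.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .seq_io import GenusDataset, SeqRecord

_BASES = np.array(list("AGCT"))  # order matches the distance encoding


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated genus.

    ``intra_depth`` / ``inter_depth`` are branch lengths in expected
    substitutions per site; the defaults (0.01 / 0.05, a 5x separation with
    expected mean distances ~2% within vs ~12% between species) describe a
    genus with clean barcoding gaps at divergence scales typical of
    congeneric arthropod COI.  ``sampling_counts`` is cycled across each
    species' haplotypes to give multiplicities, so with 8 haplotypes and the
    default (3, 2, 1) cycle a species has 8 unique haplotypes among 17
    sequences.  ``shared_haplotype_pairs`` forces the first haplotype of the
    second species in each pair to be a verbatim copy from the first species.
    """

    genus_name: str = "Simulus"
    n_species: int = 5
    seq_length: int = 600
    kappa: float = 2.0
    intra_depth: float = 0.01
    inter_depth: float = 0.05
    haplotypes_per_species: tuple[int, ...] | None = None  # default: 8 each
    sampling_counts: tuple[int, ...] = (3, 2, 1)
    shared_haplotype_pairs: tuple[tuple[str, str], ...] = ()
    missing_end_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intra_depth < 0 or self.inter_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("n_species and seq_length must be >= 1")
        if any(c < 1 for c in self.sampling_counts):
            raise ValueError("sampling counts must be >= 1")
        if not (0 <= self.missing_end_fraction <= 1):
            raise ValueError("missing_end_fraction must be in [0, 1]")

    @property
    def species_names(self) -> list[str]:
        return [f"{self.genus_name}_sp{k + 1:02d}" for k in range(self.n_species)]

    @property
    def haplotype_counts(self) -> tuple[int, ...]:
        if self.haplotypes_per_species is None:
            return (8,) * self.n_species
        if len(self.haplotypes_per_species) != self.n_species:
            raise ValueError("haplotypes_per_species length must equal n_species")
        return self.haplotypes_per_species


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    species_of: dict[str, str]  # sequence id -> true species
    haplotype_of: dict[str, str]  # sequence id -> true haplotype id
    ancestors: dict[str, str]  # species -> ancestor residues
    root: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"id": i, "true_species": self.species_of[i], "true_haplotype": self.haplotype_of[i]}
                for i in sorted(self.species_of)
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def transition_matrix(depth: float, kappa: float) -> np.ndarray:
    """Substitution probability matrix P = expm(Q * depth), states A,G,C,T.

    Rates: transition kappa*beta, each transversion beta, with beta chosen so
    the total substitution rate per site is 1 (depth = expected subs/site).
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    Q = np.full((4, 4), beta)
    for i, j in ((0, 1), (1, 0), (2, 3), (3, 2)):  # A<->G, C<->T
        Q[i, j] = alpha
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return expm(Q * depth)


def _evolve(codes: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a descendant of ``codes`` (0..3 per site) under matrix P."""
    u = rng.random(codes.size)
    cum = np.cumsum(P[codes], axis=1)
    return (u[:, None] < cum).argmax(axis=1).astype(np.int8)


def simulate_genus(cfg: SimConfig) -> tuple[GenusDataset, SimTruth]:
    """Simulate one genus alignment plus its ground truth; deterministic by seed."""
    for a, b in cfg.shared_haplotype_pairs:
        if a not in cfg.species_names or b not in cfg.species_names:
            raise ValueError(f"shared haplotype pair names unknown species: {(a, b)}")
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    root = rng.integers(0, 4, size=L).astype(np.int8)
    P_inter = transition_matrix(cfg.inter_depth, cfg.kappa)
    P_intra = transition_matrix(cfg.intra_depth, cfg.kappa)

    ancestors: dict[str, np.ndarray] = {}
    hap_codes: dict[str, list[np.ndarray]] = {}
    for sp, n_hap in zip(cfg.species_names, cfg.haplotype_counts):
        anc = _evolve(root, P_inter, rng)
        ancestors[sp] = anc
        hap_codes[sp] = [_evolve(anc, P_intra, rng) for _ in range(n_hap)]

    for a, b in cfg.shared_haplotype_pairs:
        hap_codes[b][0] = hap_codes[a][0].copy()

    records: list[SeqRecord] = []
    species_of: dict[str, str] = {}
    haplotype_of: dict[str, str] = {}
    rows: list[tuple[str, str, str]] = []  # (id, species, residues) before missing blocks
    for sp in cfg.species_names:
        for h, codes in enumerate(hap_codes[sp]):
            hap_id = f"{sp}_h{h + 1:02d}"
            mult = cfg.sampling_counts[h % len(cfg.sampling_counts)]
            residues = "".join(_BASES[codes])
            for k in range(mult):
                seq_id = f"{hap_id}_r{k + 1:02d}"
                rows.append((seq_id, sp, residues))
                species_of[seq_id] = sp
                haplotype_of[seq_id] = hap_id

    if cfg.missing_end_fraction > 0:
        n_missing = int(round(cfg.missing_end_fraction * len(rows)))
        hit = rng.choice(len(rows), size=n_missing, replace=False)
        max_block = max(1, L // 10)
        for k in hit:
            seq_id, sp, residues = rows[k]
            lead = int(rng.integers(1, max_block + 1))
            trail = int(rng.integers(1, max_block + 1))
            residues = "N" * lead + residues[lead : L - trail] + "N" * trail
            rows[k] = (seq_id, sp, residues)

    for seq_id, sp, residues in rows:
        records.append(SeqRecord(id=seq_id, genus=cfg.genus_name, species=sp, residues=residues))

    truth = SimTruth(
        species_of=species_of,
        haplotype_of=haplotype_of,
        ancestors={sp: "".join(_BASES[a]) for sp, a in ancestors.items()},
        root="".join(_BASES[root]),
    )
    return GenusDataset(cfg.genus_name, tuple(records), L), truth


@dataclass(frozen=True)
class ExpectedSummaries:
    """Closed-form expectations for calibration checks (±tolerance band)."""

    mean_intra: float
    mean_inter: float
    tolerance: float = 0.15


def expected_summaries(cfg: SimConfig) -> ExpectedSummaries:
    """Expected genus mean intra/inter distances from branch additivity.

    Two conspecific haplotypes sit on independent branches of length
    ``intra_depth`` from their ancestor, so their expected separation is
    2*intra_depth; heterospecific sequences add the two ``inter_depth``
    branches.  Valid while distances stay far from saturation; a total
    expected distance >= 0.75 substitutions/site triggers an error because
    the K2P correction becomes unstable there.
    """
    mean_intra = 2.0 * cfg.intra_depth
    mean_inter = 2.0 * cfg.inter_depth + 2.0 * cfg.intra_depth
    if mean_inter >= 0.75:
        raise ValueError(
            f"expected inter distance {mean_inter:.2f} is near saturation; "
            "closed-form calibration is unreliable"
        )
    return ExpectedSummaries(mean_intra=mean_intra, mean_inter=mean_inter)
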