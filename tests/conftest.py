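"""Shared fixtures: tiny hand-built datasets and seeded simulations."""

from __future__ import annotations

import pytest

from barcodegap.seq_io import GenusDataset, SeqRecord
from barcodegap.simulate import SimConfig, simulate_genus


def make_dataset(genus: str, rows: list[tuple[str, str, str]]) -> GenusDataset:
    """Build a GenusDataset from (id, species, residues) rows."""
    records = tuple(
        SeqRecord(id=i, genus=genus, species=sp, residues=res) for i, sp, res in rows
    )
    return GenusDataset(genus, records, len(rows[0][2]))


@pytest.fixture
def two_species_ds() -> GenusDataset:
    """Two clearly separated species, 3 sequences each, 12 bp."""
    return make_dataset(
        "Testus",
        [
            ("a1", "sp_a", "ACGTACGTACGT"),
            ("a2", "sp_a", "ACGTACGTACGA"),
            ("a3", "sp_a", "ACGTACGTACGT"),
            ("b1", "sp_b", "TGCATGCATGCA"),
            ("b2", "sp_b", "TGCATGCATGCC"),
            ("b3", "sp_b", "TGCATGCATGCA"),
        ],
    )


@pytest.fixture(scope="session")
def sim_genus():
    """Default simulated genus (5 species x 8 haplotypes, 5x separation)."""
    cfg = SimConfig(seed=42)
    ds, truth = simulate_genus(cfg)
    return cfg, ds, truth
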