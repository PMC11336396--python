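import numpy as np
import pytest

from taxodiag.alignment import AlignedSequence, Alignment, RegionMap
from taxodiag.simulate import planted_recovery_config, simulate_dataset


def make_alignment(rows: dict[str, str],
                   species: dict[str, str] | None = None,
                   genus: dict[str, str] | None = None) -> Alignment:
    members = []
    for acc, seq in rows.items():
        labels = {}
        if species and acc in species:
            labels["species"] = species[acc]
        if genus and acc in genus:
            labels["genus"] = genus[acc]
        members.append(AlignedSequence(acc, seq, labels))
    return Alignment(members)


def random_alignment(rng: np.random.Generator, n_seqs: int, n_cols: int,
                     n_species: int, gap_frac: float = 0.02,
                     ambig_frac: float = 0.0) -> Alignment:
    """Random alignment with species labels sp01..spNN assigned round-robin."""
    alphabet = np.array(list("ACGT"), dtype="U1")
    base = alphabet[rng.integers(0, 4, size=n_cols)]
    members = {}
    species = {}
    for i in range(n_seqs):
        chars = base.copy()
        mutate = rng.random(n_cols) < 0.1
        chars[mutate] = alphabet[rng.integers(0, 4, size=int(mutate.sum()))]
        gaps = rng.random(n_cols) < gap_frac
        chars[gaps] = "-"
        if ambig_frac:
            amb = rng.random(n_cols) < ambig_frac
            pool = np.array(list("RYSWKMN"), dtype="U1")
            chars[amb & ~gaps] = pool[rng.integers(0, len(pool),
                                                   size=int((amb & ~gaps).sum()))]
        acc = f"seq{i:02d}"
        members[acc] = "".join(chars)
        species[acc] = f"sp{i % n_species + 1:02d}"
    return make_alignment(members, species)


@pytest.fixture
def toy_alignment() -> Alignment:
    # 40 columns, two species; sp01 = {s1, s2}, sp02 = {s3}, outlier s4
    rows = {
        "s1": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT",
        "s2": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGA",
        "s3": "ACGTACGTACCTACGTACGTACGAACGTACGTACGTACGT",
        "s4": "TTTTACGTACGTACGTACGTACGTACGTACGTACGTAAAA",
    }
    species = {"s1": "spA", "s2": "spA", "s3": "spB", "s4": "spC"}
    return make_alignment(rows, species)


@pytest.fixture
def toy_regions() -> RegionMap:
    return RegionMap({"ITS2": (1, 20), "LSU": (21, 40), "full": (1, 40)}, 40)


@pytest.fixture(scope="session")
def planted_dataset():
    """One planted-barcode synthetic study shared across tests."""
    return simulate_dataset(planted_recovery_config(11))
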