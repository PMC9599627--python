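import numpy as np
import pytest

from bloomshift.config import SampleSheet, SampleSpec, SimConfig, default_demo_samples
from bloomshift.simulate import generate_references, generate_reads, to_alignment_records


def n_contrast_samples(library_size: int = 20_000) -> list[SampleSpec]:
    """Two barrels x (mid, late) nitrogen-experiment layout."""
    return [
        SampleSpec("MB1", "N", "B1", "mid", library_size),
        SampleSpec("MB2", "N", "B1", "late", library_size),
        SampleSpec("MB3", "N", "B3", "mid", library_size),
        SampleSpec("MB4", "N", "B3", "late", library_size),
    ]


@pytest.fixture(scope="session")
def small_bundle():
    cfg = SimConfig(
        seed=17,
        n_taxon_groups=2,
        orfs_per_group=20,
        orf_length=300,
        dispersion=0.05,
        de_fraction=0.1,
        samples=default_demo_samples(2_000),
    )
    return generate_references(cfg)


@pytest.fixture(scope="session")
def small_alignments(small_bundle):
    return {
        s.name: to_alignment_records(generate_reads(small_bundle, s.name))
        for s in small_bundle.config.samples
    }


@pytest.fixture(scope="session")
def small_sheet(small_bundle):
    return SampleSheet.from_samples(small_bundle.config.samples)


def complement_base(b: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]


def plant_snvs(bundle, per_orf: int, freqs, rng_seed: int = 0):
    """Build a PlantedSnv list over a bundle's ORFs with given per-condition freqs.

    ``freqs`` is either a (mid, late) tuple applied to all, or a callable
    (orf_index, snv_index) -> (mid, late).
    """
    from bloomshift.config import PlantedSnv

    rng = np.random.default_rng(rng_seed)
    out = []
    for j, orf in enumerate(bundle.orf_ids):
        positions = rng.choice(
            np.arange(10, bundle.config.orf_length - 10), size=per_orf, replace=False
        )
        for i, pos in enumerate(sorted(int(p) for p in positions)):
            ref = bundle.references[orf][pos - 1]
            alt = complement_base(ref)
            f = freqs(j, i) if callable(freqs) else freqs
            out.append(
                PlantedSnv(orf, pos, ref, alt, {"mid": float(f[0]), "late": float(f[1])})
            )
    return out
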