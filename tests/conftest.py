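import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trnldiet.reference import PRIMER_G, PRIMER_H, ReferenceSequence, build_haplotype_groups
from trnldiet.simulate import SimulationConfig, simulate_study
from trnldiet.taxonomy import Taxonomy

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def small_taxonomy():
    """Three families; one genus with two species; mixed origins."""
    rows = [
        ("Morus_australis", "Morus", "Moraceae", "introduced"),
        ("Ficus_microcarpa", "Ficus", "Moraceae", "introduced"),
        ("Ficus_boninsimae", "Ficus", "Moraceae", "native"),
        ("Machilus_kobu", "Machilus", "Lauraceae", "native"),
        ("Neolitsea_aurata", "Neolitsea", "Lauraceae", "native"),
        ("Carex_hattoriana", "Carex", "Cyperaceae", "native"),
    ]
    return Taxonomy(
        pd.DataFrame(rows, columns=["species_id", "genus", "family", "origin"])
    )


def make_refs(assignments: dict[str, str]) -> list[ReferenceSequence]:
    """References with given species -> p6 sequences (primer-flanked introns)."""
    from trnldiet._utils import revcomp

    return [
        ReferenceSequence(sp, PRIMER_G + seq + revcomp(PRIMER_H), seq)
        for sp, seq in assignments.items()
    ]


@pytest.fixture
def small_reference(small_taxonomy):
    """Six species over four haplotypes: one Ficus pair shares, the two
    Lauraceae share."""
    seqs = {
        "Morus_australis": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC",
        "Ficus_microcarpa": "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATT",
        "Ficus_boninsimae": "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATT",
        "Machilus_kobu": "GGCCGGCCAATTAATTGGCCGGCCAATTAATTGGCCGGCCAATTAATTGG",
        "Neolitsea_aurata": "GGCCGGCCAATTAATTGGCCGGCCAATTAATTGGCCGGCCAATTAATTGG",
        "Carex_hattoriana": "AACCAACCGGTTGGTTAACCAACCGGTTGGTTAACCAACCGGTTGGTTAA",
    }
    refs = make_refs(seqs)
    groups = build_haplotype_groups(refs, small_taxonomy)
    return refs, groups


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at default conditions, shared across tests."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_pipeline_output(default_study, tmp_path_factory):
    """The default study pushed through the whole pipeline once."""
    from trnldiet import io as tio
    from trnldiet.config import RunConfig
    from trnldiet.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    bundle = default_study
    tio.write_fasta(
        [tio.RawRead(r.species_id, r.intron_seq) for r in bundle["references"]],
        out / "reference.fasta",
    )
    bundle["taxonomy"].to_tsv(out / "taxonomy.tsv")
    tio.write_fastq(bundle["reads"], out / "reads.fastq")
    tio.write_midmap(bundle["midmap"], out / "mids.tsv")
    tio.write_tsv(bundle["metadata"], out / "metadata.tsv")
    cfg = RunConfig(
        reference_fasta=str(out / "reference.fasta"),
        taxonomy_tsv=str(out / "taxonomy.tsv"),
        reads_path=str(out / "reads.fastq"),
        mids_tsv=str(out / "mids.tsv"),
        metadata_tsv=str(out / "metadata.tsv"),
        seed=7,
        out_dir=str(out / "results"),
    )
    return run_pipeline(cfg), cfg


def rng(seed=0):
    return np.random.default_rng(seed)
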