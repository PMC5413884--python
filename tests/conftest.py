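import pytest

from fernhnl.pipeline import RunConfig, run_discovery
from fernhnl.synthetic import (
    FixtureSpec,
    generate_peptide_evidence,
    generate_toy_structure,
    generate_transcriptome,
)


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study fixture at seed 1: transcriptome, ground
    truth and peptide evidence."""
    spec = FixtureSpec(seed=1)
    transcripts, truth = generate_transcriptome(spec)
    evidence = generate_peptide_evidence(truth, spec)
    return spec, transcripts, truth, evidence


@pytest.fixture(scope="session")
def discovery_report(default_fixture):
    """Full discovery run on the default fixture (computed once)."""
    spec, transcripts, truth, evidence = default_fixture
    report = run_discovery(
        RunConfig(seed=spec.seed),
        transcripts=transcripts,
        evidence=evidence,
        known_refs=truth.known_references,
        write_outputs=False,
    )
    return truth, report


@pytest.fixture()
def toy_model(tmp_path):
    """Toy active-site structure: 5-water chain at 2.8 A spacing."""
    from fernhnl.structure import read_pdb

    path = tmp_path / "toy.pdb"
    path.write_text(generate_toy_structure(n_waters=5, spacing=2.8))
    return read_pdb(path)
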