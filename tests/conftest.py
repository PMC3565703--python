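import pytest
from hypothesis import settings

from helixbridge.synthetic import FixtureSpec, generate_triple

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def planted_triple():
    """A deterministic synthetic triple with planted shifts +2 / -1."""
    spec = FixtureSpec(
        n_sequences=50,
        helix_lengths={"TM1": 25},
        shift_a=2,
        shift_b=-1,
        noise=0.1,
        group_conserved={"TM1": (4, 11, 18)},
        seed=7,
    )
    return generate_triple(spec)


@pytest.fixture
def small_fasta(tmp_path):
    """Write a tiny aligned FASTA + CSV region config; returns paths."""

    def write(records, regions_rows, name="fam"):
        fasta = tmp_path / f"{name}.fasta"
        fasta.write_text(
            "".join(f">{rid}\n{seq}\n" for rid, seq in records)
        )
        cfg = tmp_path / f"{name}_regions.csv"
        lines = ["family_id,helix_id,start_col,end_col,ref50_col"]
        lines += [",".join(str(x) for x in row) for row in regions_rows]
        cfg.write_text("\n".join(lines) + "\n")
        return fasta, cfg

    return write
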