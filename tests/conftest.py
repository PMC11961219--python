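import pytest
from hypothesis import strategies as st

from pepfeat import PTM_TAGS, STANDARD_AMINO_ACIDS, generate_random_peptides


@pytest.fixture(scope="session")
def random_unmodified():
    """200 seeded random unmodified peptides of mixed lengths."""
    out = []
    for i, length in enumerate(range(1, 41)):
        out.extend(generate_random_peptides(5, length, 0.0, seed=1000 + i))
    return out


@pytest.fixture(scope="session")
def random_modified():
    """200 seeded random peptides with a 20% per-residue PTM probability."""
    out = []
    for i, length in enumerate(range(1, 41)):
        out.extend(generate_random_peptides(5, length, 0.2, seed=2000 + i))
    return out


def residue_text() -> st.SearchStrategy[str]:
    """Hypothesis strategy for one residue in bracket notation."""
    def with_tag(base: str) -> st.SearchStrategy[str]:
        tags = [t for t, (_, legal) in PTM_TAGS.items() if base in legal]
        opts = st.just(base)
        if tags:
            opts = st.one_of(opts, st.sampled_from([f"{base}[{t}]" for t in tags]))
        return opts

    return st.sampled_from(STANDARD_AMINO_ACIDS).flatmap(with_tag)


def peptide_text(min_size: int = 1, max_size: int = 30) -> st.SearchStrategy[str]:
    """Hypothesis strategy for a peptide string in bracket notation."""
    return st.lists(residue_text(), min_size=min_size, max_size=max_size).map("".join)
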