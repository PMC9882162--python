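import numpy as np
import pytest

from nlrdivers.alignment import Alignment, CodonAlignment


@pytest.fixture
def toy_4x16():
    """4-sequence, 16-column nucleotide alignment with S=2 and 8 total
    pairwise differences (cols 9 and 16 polymorphic, 1-based)."""
    return Alignment(
        records=(
            ("a", "A" * 16),
            ("b", "A" * 15 + "T"),
            ("c", "A" * 8 + "T" + "A" * 7),
            ("d", "A" * 8 + "T" + "A" * 6 + "T"),
        ),
        alphabet="nucleotide",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_nt_alignment(rng, n, length, alphabet="ACGT", gap_rate=0.0):
    """Random nucleotide alignment, optionally with gaps/Ns sprinkled in."""
    chars = list(alphabet)
    mat = rng.choice(chars, size=(n, length))
    if gap_rate:
        noise = rng.random((n, length))
        mat[noise < gap_rate / 2] = "-"
        mat[(noise >= gap_rate / 2) & (noise < gap_rate)] = "N"
    return Alignment(
        records=tuple((f"s{i}", "".join(mat[i])) for i in range(n)),
        alphabet="nucleotide",
    )
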