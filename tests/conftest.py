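import itertools

import pytest

from varrel.variant_model import Representation


def canonical(rep: Representation) -> tuple:
    """Hashable canonical form of a representation for set comparison."""
    return tuple(rep.sorted().operations)


def all_strings(alphabet: str, max_len: int, min_len: int = 0) -> list[str]:
    return [
        "".join(t)
        for length in range(min_len, max_len + 1)
        for t in itertools.product(alphabet, repeat=length)
    ]


@pytest.fixture
def write_reference(tmp_path):
    def _write(sequence: str, fasta: bool = True, name: str = "ref"):
        path = tmp_path / f"{name}.fa"
        if fasta:
            path.write_text(f">{name} test sequence\n{sequence}\n")
        else:
            path.write_text(sequence + "\n")
        return path

    return _write
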