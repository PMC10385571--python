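import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pamap2_rows(n_rows: int, activity_id: int = 4, seed: int = 0,
                     fs: float = 100.0) -> str:
    """Render valid 54-column PAMAP2-format text rows."""
    rng = np.random.default_rng(seed)
    lines = []
    for i in range(n_rows):
        row = [f"{i / fs:.2f}", str(activity_id), "100"]
        row += [f"{v:.4f}" for v in rng.normal(0, 1, 51)]
        lines.append(" ".join(row))
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_pamap2_file(tmp_path):
    path = tmp_path / "toy.dat"
    path.write_text(make_pamap2_rows(3))
    return path
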