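import numpy as np
import pytest

from cyclefe import ExpressionMatrix, normalize_samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, gene_ids=None, time_labels=None, **kw):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i + 1}" for i in range(n)],
        time_labels=time_labels or [str(j + 1) for j in range(m)],
        values=values,
        **kw,
    )


@pytest.fixture
def random_normalized():
    """A 50×10 per-sample-normalized random matrix."""
    rng = np.random.default_rng(7)
    return normalize_samples(make_matrix(rng.normal(size=(50, 10))))


@pytest.fixture
def tsv_file(tmp_path):
    """Write a small gene × time TSV and return (path, values)."""

    def _write(values, gene_ids=None, time_labels=None, line_ending="\n"):
        values = np.asarray(values, dtype=float)
        n, m = values.shape
        gene_ids = gene_ids or [f"g{i + 1}" for i in range(n)]
        time_labels = time_labels or [f"t{j + 1}" for j in range(m)]
        lines = ["gene_id\t" + "\t".join(time_labels)]
        for g, row in zip(gene_ids, values):
            lines.append(g + "\t" + "\t".join(repr(float(v)) for v in row))
        path = tmp_path / "matrix.tsv"
        path.write_bytes((line_ending.join(lines) + line_ending).encode())
        return path

    return _write
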