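import numpy as np
import pytest

from prism_atac import FixtureSpec, generate_null_universe


@pytest.fixture(scope="session")
def small_universe():
    """Desk-scale null universe shared by resampling-heavy tests."""
    spec = FixtureSpec.default(n_cells=120, n_peaks=800, seed=11)
    return generate_null_universe(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_mtx(path, n_rows, n_cols, entries):
    """Minimal matrix-market coordinate file; entries are 1-based (i, j, v)."""
    with open(path, "wt") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{n_rows} {n_cols} {len(entries)}\n")
        for i, j, v in entries:
            fh.write(f"{i} {j} {v}\n")


@pytest.fixture()
def bundle_writer(tmp_path):
    """Write an (mtx, bed, barcodes) triple and return the three paths."""

    def _write(n_rows, n_cols, entries, peaks, barcodes, suffix=""):
        mtx = tmp_path / f"m{suffix}.mtx"
        bed = tmp_path / f"p{suffix}.bed"
        bc = tmp_path / f"b{suffix}.txt"
        write_mtx(mtx, n_rows, n_cols, entries)
        with open(bed, "wt") as fh:
            for row in peaks:
                fh.write("\t".join(str(x) for x in row) + "\n")
        with open(bc, "wt") as fh:
            fh.write("\n".join(barcodes) + "\n")
        return mtx, bed, bc

    return _write
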