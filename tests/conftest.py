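import hypothesis
import numpy as np
import pandas as pd
import pytest

from ticquant.quantify import ExpressionMatrix, SampleInfo

hypothesis.settings.register_profile(
    "ticquant", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("ticquant")


DESIGN_1REP = {"wt_1": SampleInfo("wt", 1), "mut_1": SampleInfo("mutant", 1)}
DESIGN_2REP = {
    "wt_1": SampleInfo("wt", 1),
    "wt_2": SampleInfo("wt", 2),
    "mut_1": SampleInfo("mutant", 1),
    "mut_2": SampleInfo("mutant", 2),
}


@pytest.fixture
def design_1rep():
    return dict(DESIGN_1REP)


@pytest.fixture
def design_2rep():
    return dict(DESIGN_2REP)


def matrix_from_log2(log2_rows, design, protein_ids=None):
    """Build an ExpressionMatrix from a list of per-protein log2 tuples."""
    arr = np.asarray(log2_rows, dtype=float)
    ids = protein_ids or [f"P{i:04d}" for i in range(1, len(arr) + 1)]
    tic = pd.DataFrame(2.0**arr, index=ids, columns=list(design))
    tic.index.name = "protein_id"
    return ExpressionMatrix(tic=tic, design=design)


@pytest.fixture
def make_matrix():
    return matrix_from_log2


def write_psm_tsv(path, rows):
    """Write a PSM TSV from (protein, peptide, charge, mz, rt, intensity, sample, log_e, mc) tuples."""
    header = "protein_id\tpeptide\tcharge\tparent_mz\tretention_time\tfragment_intensity_sum\tsample_id\tlog_e\tmissed_cleavages"
    lines = [header] + ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def psm_writer(tmp_path):
    def _write(rows, name="psms.tsv"):
        return write_psm_tsv(tmp_path / name, rows)

    return _write
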