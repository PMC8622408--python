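import sys
from pathlib import Path

import hypothesis
import pytest

sys.path.insert(0, str(Path(__file__).parent))

hypothesis.settings.register_profile(
    "cresscan", deadline=None, derandomize=True, max_examples=50)
hypothesis.settings.load_profile("cresscan")


@pytest.fixture(scope="session")
def cn9e_style():
    """Synthetic genome emulating the 1826-nt table-5 spliced-Rep
    architecture (ATA start, 56-nt intron, no 3'-IR)."""
    from cresscan.synthetic import GenomeSpec, generate_genome
    spec = GenomeSpec(seed=11, genome_len=1826, rep_len_aa=292,
                      cp_len_aa=258, rep_table=5, rep_start_codon="ATA",
                      intron_len=56, ir3_len=0)
    return generate_genome(spec)


@pytest.fixture(scope="session")
def cn16e_style():
    """Synthetic genome emulating the 1909-nt standard-code architecture
    (TACTATTAC motif, 280-aa Rep, 295-aa Cp, 4-nt 3'-IR)."""
    from cresscan.synthetic import GenomeSpec, generate_genome
    spec = GenomeSpec(seed=5, genome_len=1909, motif="TACTATTAC",
                      rep_len_aa=280, cp_len_aa=295, ir3_len=4)
    return generate_genome(spec)
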