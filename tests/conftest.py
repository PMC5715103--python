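import numpy as np
import pytest

from strseek.catalog import STRLocus


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def repeatmasker_fixture():
    """A 5-row .out snippet: 2 Simple_repeat rows among LINE/SINE/LTR rows,
    with the hand-parsed expected loci."""
    text = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
        " 1504  12.1   6.0   1.0  chr1      10001    10468 (249240153) +  L1MA4"
        "            LINE/L1               1  471 (241)    1\n"
        "  239   1.2   0.0   0.0  chr2   74144317 74144336 (0)  +  (TAAA)n"
        "          Simple_repeat         1   20 (0)       2\n"
        "  301  29.4   1.9   1.1  chr1      10628    10757 (249239864) C  AluSx"
        "            SINE/Alu              1  130 (0)      3\n"
        "  180   6.3   0.5   0.2  chr9   79400651 79400676 (0)  C  (ca)n"
        "           Simple_repeat         1   26 (0)       4\n"
        "  812  18.0   2.1   0.3  chr3      20000    20500 (100)  +  MLT1B"
        "            LTR/ERVL              1  501 (0)      5\n"
    )
    expected = [
        STRLocus("chr2", 74144316, 74144336, "TAAA", 4, "+", 1.2, 0.0, 0.0),
        STRLocus("chr9", 79400650, 79400676, "CA", 2, "-", 6.3, 0.5, 0.2),
    ]
    return text, expected


def random_locus(rng, chrom="chr1", motifs=("TG", "CA", "AT", "TAAA", "CAG", "A")):
    motif = motifs[rng.integers(0, len(motifs))]
    start = int(rng.integers(0, 100_000))
    length = int(rng.integers(1, 60)) + len(motif)
    return STRLocus(
        chrom=chrom,
        start=start,
        end=start + length,
        motif=motif,
        period=len(motif),
        strand="+" if rng.random() < 0.5 else "-",
        pct_div=float(rng.uniform(0, 20)),
        pct_del=float(rng.uniform(0, 20)),
        pct_ins=float(rng.uniform(0, 20)),
    )
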