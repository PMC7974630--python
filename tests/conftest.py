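import numpy as np
import pytest

from puseq import GenomeLayout, PolymeraseTrack


@pytest.fixture
def layout3():
    """A 3-bin, 900 bp single-chromosome layout (300 bp bins)."""
    return GenomeLayout((("chrI", 900),), 300)


@pytest.fixture
def layout_two_chroms():
    return GenomeLayout((("chrI", 3000), ("chrII", 1500)), 300)


def make_track(layout, polymerase, values_by_chrom, flags_by_chrom=None):
    """Build a PolymeraseTrack from raw per-chromosome value arrays."""
    values = {c: np.asarray(values_by_chrom[c], dtype=float) for c in layout.names}
    if flags_by_chrom is None:
        flags = {c: np.zeros(layout.n_bins(c), dtype=bool) for c in layout.names}
    else:
        flags = {c: np.asarray(flags_by_chrom[c], dtype=bool) for c in layout.names}
    return PolymeraseTrack(layout, polymerase, values, flags)


def tracks_from_f_right(layout, f_right_by_chrom):
    """Noise-free expected tracks for all three polymerases from f_right."""
    from puseq import expected_track

    return {
        pol: make_track(
            layout, pol,
            {c: expected_track(f_right_by_chrom[c], pol) for c in layout.names},
        )
        for pol in ("delta", "epsilon", "alpha")
    }
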