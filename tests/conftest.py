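import numpy as np
import pytest

from revmet import chemlib as cl
from revmet.spectra import Spectrum


@pytest.fixture(scope="session")
def blocks_index():
    idx = cl.bundled_block_index()
    # glycine is deliberately not in the 22-amino-acid scheme table, but the
    # classic Gly conjugates are useful references
    idx["Gly"] = cl.BuildingBlock("Gly", "amino_acid", cl.parse_formula("C2H5NO2"))
    return idx


@pytest.fixture(scope="session")
def bile_library():
    """Full 8 x 22 bile-amidate library with [M+H]+ adducts."""
    return cl.enumerate_library(
        cl.bundled_blocks("bile_acids"),
        cl.bundled_blocks("amino_acids"),
        cl.CONDENSATION_RULES["bile_amidate"],
        [cl.ADDUCTS["[M+H]+"]],
    )


@pytest.fixture(scope="session")
def distinct_mass_library():
    """A sub-library with pairwise distinct product formulas.

    One bile core per hydroxylation state and amino acids without
    mass-degenerate pairs, so search results can be compared to the
    simulator ledger cell-for-cell.
    """
    bile = [b for b in cl.bundled_blocks("bile_acids") if b.name in ("CA", "CDCA")]
    # avoid cross-core collisions: CA+X collides with CDCA+(X plus one O),
    # so no amino-acid pair here differs by exactly one oxygen
    keep = {"Ala", "Ile", "Val", "Thr", "Glu", "Lys", "Met", "His", "Phe", "Trp"}
    amino = [a for a in cl.bundled_blocks("amino_acids") if a.name in keep]
    lib = cl.enumerate_library(
        bile, amino, cl.CONDENSATION_RULES["bile_amidate"], [cl.ADDUCTS["[M+H]+"]])
    assert all(r.mass_degenerate_group is None for r in lib)
    return lib


def make_spectrum(mz, intensities, spectrum_id="s", precursor_mz=500.0, **kwargs):
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz,
        mz=np.asarray(mz, dtype=float),
        intensities=np.asarray(intensities, dtype=float),
        **kwargs,
    )


@pytest.fixture
def spectrum_factory():
    return make_spectrum
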