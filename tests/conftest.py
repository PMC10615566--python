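import numpy as np
import pandas as pd
import pytest

from popscan.genio import HaplotypePanel


def build_panel(
    haplotypes,
    cm=None,
    bp=None,
    chrom="1",
    sample_ids=None,
    ancestral_ok=None,
    missing=None,
) -> HaplotypePanel:
    """Construct a HaplotypePanel from a raw 0/1 matrix with sensible
    defaults for variant metadata (1 cM/Mb map)."""
    H = np.asarray(haplotypes, dtype=np.uint8)
    n_hap, m = H.shape
    assert n_hap % 2 == 0
    if cm is None:
        cm = np.arange(1, m + 1) * 0.01
    cm = np.asarray(cm, dtype=float)
    if bp is None:
        bp = np.round(cm * 1_000_000).astype(int)
    if sample_ids is None:
        sample_ids = [f"s{i:03d}" for i in range(n_hap // 2)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "bp": bp,
            "cM": cm,
            "ref": "A",
            "alt": "G",
            "ancestral_is_ref": True,
            "ancestral_ok": True if ancestral_ok is None else ancestral_ok,
        }
    )
    return HaplotypePanel(H, sample_ids, variants, missing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
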