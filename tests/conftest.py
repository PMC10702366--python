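import numpy as np
import pandas as pd
import pytest

from kinmotif.library import AMINO_ACIDS, FLANK_POSITIONS, PSSM, KinaseLibrary
from kinmotif.simulate import make_library


def uniform_matrix() -> pd.DataFrame:
    n = len(AMINO_ACIDS)
    return pd.DataFrame(np.full((len(FLANK_POSITIONS), n), 1.0 / n),
                        index=list(FLANK_POSITIONS), columns=list(AMINO_ACIDS))


@pytest.fixture
def uniform_pssm() -> PSSM:
    return PSSM("UNIFORM", uniform_matrix())


@pytest.fixture
def tiny_library() -> KinaseLibrary:
    return make_library(n_kinases=3, sharpness=4.0, seed=7)


def peaked_pssm(kinase: str, flank: str, p_match: float = 0.9) -> PSSM:
    """PSSM whose per-position argmax residues spell the given flank."""
    mat = uniform_matrix().copy()
    rest = (1.0 - p_match) / (len(AMINO_ACIDS) - 1)
    for pos in FLANK_POSITIONS:
        aa = flank[pos + 5]
        if aa == "_":
            continue
        mat.loc[pos] = rest
        mat.loc[pos, aa] = p_match
    return PSSM(kinase, mat)


def make_records(rows: list[dict], n_channels: int = 4) -> pd.DataFrame:
    """Build a reporter-record table from per-row overrides of passing defaults."""
    channels = [f"ch{i:02d}" for i in range(1, n_channels + 1)]
    out = []
    for i, row in enumerate(rows):
        base = {
            "record_id": f"R{i + 1:06d}",
            "site_id": row.get("site_id", f"P{i + 1:05d}_S10"),
            "protein_id": row.get("protein_id", f"P{i + 1:05d}"),
            "isolation_specificity": 0.95,
            "localization_score": 30.0,
            "n_phospho": 1,
        }
        intensities = row.get("intensities", [100.0] * n_channels)
        base.update({ch: v for ch, v in zip(channels, intensities)})
        base.update({k: v for k, v in row.items()
                     if k not in {"intensities"}})
        vals = np.array([base[ch] for ch in channels], dtype=float)
        base.setdefault("summed_sn", float(np.nansum(vals)))
        base["n_missing_channels"] = int(np.isnan(vals).sum())
        out.append(base)
    return pd.DataFrame(out)


# --- independent oracles (deliberately coded apart from the implementation) ---

def bh_stepup_oracle(pvals) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up, coded independently."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact hypergeometric upper tail by integer enumeration."""
    from math import comb
    n_reg, n_unreg, n_pred = a + b, c + d, a + c
    total = a + b + c + d
    if n_reg == 0 or n_pred == 0 or a == 0:
        return 1.0
    denom = comb(total, n_pred)
    num = sum(comb(n_reg, j) * comb(n_unreg, n_pred - j)
              for j in range(a, min(n_reg, n_pred) + 1)
              if 0 <= n_pred - j <= n_unreg)
    return num / denom
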