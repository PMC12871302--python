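"""Relative gene expression by the ddCt (Livak) method.

dCt(sample) = Ct(target) - Ct(housekeeping); ddCt(genotype) =
mean dCt(genotype) - mean dCt(reference); relative expression =
2^(-ddCt), so the reference genotype is exactly 1.  No
amplification-efficiency correction is applied.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["delta_delta_ct"]


def _delta_ct(table: pd.DataFrame, target_gene: str,
              housekeeping_gene: str) -> pd.DataFrame:
    wide = table.pivot_table(index=["genotype", "sample_id"], columns="gene",
                             values="ct", aggfunc="mean")
    for g in (target_gene, housekeeping_gene):
        if g not in wide.columns or wide[g].isna().any():
            raise ValueError(f"gene {g!r} missing for some sample")
    out = wide[[target_gene]].copy()
    out["delta_ct"] = wide[target_gene] - wide[housekeeping_gene]
    return out.reset_index()


def delta_delta_ct(table: pd.DataFrame, target_gene: str = "KIF1A",
                   housekeeping_gene: str = "GAPDH",
                   reference_genotype: str = "WT",
                   per_sample: bool = False) -> pd.Series:
    """Per-genotype relative expression of ``target_gene`` vs the reference.

    ``table`` is tidy with columns sample_id, genotype, gene, ct.  By
    default dCt values are averaged per genotype before ddCt (Livak form);
    with ``per_sample`` each sample's 2^(-ddCt) is computed against the
    reference mean and then averaged.
    """
    required = {"sample_id", "genotype", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    d = _delta_ct(table, target_gene, housekeeping_gene)
    if reference_genotype not in set(d.genotype):
        raise ValueError(f"reference genotype {reference_genotype!r} absent")
    ref_mean = d.loc[d.genotype == reference_genotype, "delta_ct"].mean()
    if per_sample:
        d["rel"] = 2.0 ** (-(d.delta_ct - ref_mean))
        rel = d.groupby("genotype")["rel"].mean()
    else:
        ddct = d.groupby("genotype")["delta_ct"].mean() - ref_mean
        rel = 2.0 ** (-ddct)
        rel.loc[reference_genotype] = 1.0  # exact by construction
    rel.name = f"rel_expr_{target_gene}"
    return rel
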