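"""Rank two multiplex families by unexplained disease burden.

Both families have three affected members, but family HIGHRISK carries
many risk alleles at the known loci (its burden is expected) while
family LOWRISK carries few (its burden is surprising).  The burden
statistic P(Y >= y_obs | observed genotypes) ranks LOWRISK first for
sequencing, and integrates over the ungenotyped mother in LOWRISK via
conditional genotype sampling.
"""

import numpy as np

from prioriseq import (
    VariantPanel,
    burden_statistic,
    calibrate_intercept,
    rank_families,
)
from prioriseq.pedigree import AFFECTED, Individual, ObservedGenotypes, Pedigree

panel = VariantPanel(
    variant_id=["rs1", "rs2", "rs3"],
    effect_allele=["A", "A", "A"],
    other_allele=["G", "G", "G"],
    freq=[0.3, 0.2, 0.4],
    effect=[np.log(2.0), np.log(1.8), np.log(1.5)],
    effect_type="logOR",
)
K = 0.05
alpha = calibrate_intercept(panel, K)


def family(fid, dosages_by_member):
    members = [
        Individual("dad", None, None, 1, AFFECTED),
        Individual("mum", None, None, 2, AFFECTED),
        Individual("kid", "dad", "mum", 1, AFFECTED),
    ]
    obs = ObservedGenotypes(
        locus_ids=panel.variant_id,
        dosages={k: np.asarray(v, float) for k, v in dosages_by_member.items()},
    )
    return Pedigree(members=members, family_id=fid), obs


high = family("HIGHRISK", {"dad": [2, 2, 2], "mum": [2, 1, 2], "kid": [2, 2, 2]})
low = family("LOWRISK", {"dad": [0, 0, 0], "kid": [0, 0, 1]})  # mum ungenotyped

results = [
    burden_statistic(*high, panel, alpha, R=20_000, seed=0),
    burden_statistic(*low, panel, alpha, R=20_000, seed=0),
]
order = rank_families(results)
print(f"population prevalence K = {K}, calibrated intercept = {alpha:.3f}\n")
print("rank  family    y_obs  P(Y>=y|G)   mc_se    E[affected|G]")
for rank, idx in enumerate(order, start=1):
    r = results[idx]
    print(f"{rank:>4}  {r.family_id:<8}  {r.y_obs:>4}   {r.p_tail:.3e}  "
          f"{r.mc_se:.1e}   {r.expected_affected:.3f}")
print("\nLOWRISK's three affected members are far less probable given its")
print("genotypes, so it is the better candidate for sequencing.")
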