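"""Exact genotype posteriors and conditional sampling in a pedigree.

Builds a three-generation pedigree in which only three members are
genotyped at one locus, computes every member's exact marginal
genotype posterior by the inside-outside recursion, and draws
Mendelian-consistent genotype replicates conditional on the observed
data — the machinery that lets risk prediction run on partially
genotyped families.
"""

import numpy as np

from prioriseq import inside_pass, outside_pass, sample_genotypes
from prioriseq.pedigree import Individual, ObservedGenotypes, Pedigree

ped = Pedigree(
    members=[
        Individual("grandpa", None, None, 1),
        Individual("grandma", None, None, 2),
        Individual("dad", "grandpa", "grandma", 1),
        Individual("mum", None, None, 2),
        Individual("kid1", "dad", "mum", 1),
        Individual("kid2", "dad", "mum", 2),
    ],
    family_id="DEMO",
)
obs = ObservedGenotypes(
    locus_ids=["rs1"],
    dosages={"grandpa": np.array([2.0]),
             "mum": np.array([0.0]),
             "kid1": np.array([1.0])},
)
f = 0.2  # population effect-allele frequency

tables = inside_pass(ped, obs, f)
post = outside_pass(tables)
print(f"log-likelihood of the observed genotypes: {tables.loglik:.4f}\n")
print("member     P(g=0)  P(g=1)  P(g=2)")
for i, iid in enumerate(post.member_ids):
    p = post.marginal[i, 0]
    tag = "observed" if iid in obs.dosages else "inferred"
    print(f"{iid:<9}  {p[0]:.4f}  {p[1]:.4f}  {p[2]:.4f}   ({tag})")

samp = sample_genotypes(ped, obs, f, R=20_000, seed=1)
emp = (samp.dosages[:, ped.index("kid2"), 0][:, None] == np.arange(3)).mean(0)
print(f"\nkid2 empirical frequencies over 20,000 replicates: "
      f"{emp[0]:.4f}  {emp[1]:.4f}  {emp[2]:.4f}")
print("Sampling reproduces the exact posterior; every replicate is a full")
print("Mendelian-consistent genotype assignment usable for risk prediction.")
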