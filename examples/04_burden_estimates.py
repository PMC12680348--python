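"""Per-genome fitness-burden bookkeeping: de novo STRs vs. SNVs.

Computes the expected fitness burden of one generation of de novo mutations
for SNV categories (Burden = 2 * L * mu * s) and for an illustrative STR
class (locus count x 2 x mutation rate x expected per-mutation fitness
cost), then compares against the reference genome-wide STR aggregate. STR
burdens are "scaled" (s halved) so they sit on the SNV heterozygote scale.

Also demonstrates the frequency-weighted draw used when scoring inherited
STR alleles: an allele common in the population today must come from the
neutral tail of the class DFE.
"""

from strsel.burden import (
    CONSERVED_NONCODING_SNVS,
    GENOMEWIDE_STR_BURDEN_SCALED,
    GENOMEWIDE_STR_MEAN_S_SCALED,
    GENOMEWIDE_STR_MUTATIONS_PER_GEN,
    NONSYNONYMOUS_SNVS,
    StrClassRecord,
    denovo_snv_burden,
    denovo_str_class_burden,
    noncoding_snv_record,
    table_draw_probabilities,
)

print("De novo SNV burdens (mean s x expected mutations/generation):")
for rec in (NONSYNONYMOUS_SNVS, CONSERVED_NONCODING_SNVS):
    print(f"  {rec.label:20s} s={rec.mean_s:<8g} mut/gen={rec.expected_mutations:<5g}"
          f" burden={denovo_snv_burden(rec):.4f}")
for frac in (0.20, 0.30):
    rec = noncoding_snv_record(frac)
    print(f"  {rec.label:20s} s={rec.mean_s:<8g} mut/gen={rec.expected_mutations:<5.3g}"
          f" burden={denovo_snv_burden(rec):.5f}")

print()
print(f"Reference genome-wide de novo STR burden (scaled): "
      f"{GENOMEWIDE_STR_BURDEN_SCALED} from "
      f"{GENOMEWIDE_STR_MUTATIONS_PER_GEN} mutations/generation")
ratio = NONSYNONYMOUS_SNVS.mean_s / GENOMEWIDE_STR_MEAN_S_SCALED
print(f"  -> one nonsynonymous SNV is ~{ratio:.0f}x as deleterious as one STR")
print(f"     mutation, but STRs mutate so often their total burden is "
      f"{GENOMEWIDE_STR_BURDEN_SCALED / denovo_snv_burden(NONSYNONYMOUS_SNVS):.1f}x larger.")

print()
print("One STR class in isolation (1,000 AC loci, mu=1e-4, mean s=1e-3, rho=0.9):")
rec = StrClassRecord(("AC", 11), n_loci=1000, mu_opt=1e-4, rho=0.9,
                     mean_s=1e-3, ks_score=90)
cb = denovo_str_class_burden(rec, scaled=True)
print(f"  class burden (scaled) = {cb.value:.3e}; "
      f"geometric step mass dropped beyond 20 units = {cb.truncation_deficit:.2e}")

print()
print("Inherited-allele s: frequency-weighted draw over simulated (s, freq) pairs")
pairs = [(0.0001, 0.5), (0.001, 0.2), (0.01, 0.1)]
probs = table_draw_probabilities(pairs)
for (s, f), p in zip(pairs, probs):
    print(f"  s={s:<7g} allele freq={f:<4g} -> drawn with probability {p:.3f}")
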