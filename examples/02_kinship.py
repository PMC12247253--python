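"""Kinship and relatedness on a small hand-built pedigree.

phi(a, b) is the probability that random alleles drawn from a and b are
identical by descent; relatedness r = 2*phi (percent) is the expected
fraction of alleles a dam and sire share.  The classical values printed
here (50% for parent-offspring and full sibs, 25% for half sibs) are the
standard checks for any pedigree implementation.
"""

from colonykin import Pedigree, kinship, pair_relatedness

# F1-F3 founders; C and D full sibs; H a half sib of C; X from the
# full-sib mating C x D
ped = Pedigree({"C": ("F1", "F2"), "D": ("F1", "F2"), "H": ("F1", "F3"), "X": ("C", "D")})

for a, b, label in [
    ("F1", "C", "parent-offspring"),
    ("C", "D", "full siblings"),
    ("C", "H", "half siblings"),
]:
    phi = kinship(ped, a, b)
    print(f"{label:24s} phi = {phi:.4f}   relatedness = {200 * phi:5.1f}%")
# self-kinship exceeds 1/2 only for inbred individuals (phi(x,x) = (1+F)/2)
print(f"{'self, X (F = 0.25)':24s} phi = {kinship(ped, 'X', 'X'):.4f}")

# batch interface used by the pipeline: unknown parents give missing values
results = pair_relatedness(ped, [("C", "D"), ("C", None)])
print("\nbatch:", [(r.dam_id, r.sire_id, r.relatedness_pct) for r in results])
print("\nA missing sire yields a missing relatedness, not zero: those pairs")
print("are excluded from relatedness analyses rather than biasing them.")
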