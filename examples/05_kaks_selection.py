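"""Ka/Ks selection analysis of duplicate gene pairs.

Nei–Gojobori codon counting with Jukes–Cantor correction: Ka/Ks < 1
means purifying selection, = 1 neutral, > 1 positive.  The synthetic
pairs were evolved under known selection intensities (omega), so the
calls can be scored against truth.
"""

import numpy as np

from kinomics import kaks
from kinomics.simulate import SimConfig, evolve_cds_pair, gen_genome, \
    random_cds

bundle = gen_genome(SimConfig(), seed=1)
print("pair                      omega   Ka/Ks   call")
for (ga, gb), omega in sorted(bundle.truth.true_omega.items()):
    r = kaks.kaks_pair(bundle.cds[ga + ".1"], bundle.cds[gb + ".1"])
    ratio = f"{r.ratio:.3f}" if r.ratio is not None else "undef"
    print(f"{ga} vs {gb}   {omega:>4.1f}   {ratio:>6}   {r.selection}")

# controlled check: evolve one 600-codon CDS at three intensities
print("\ncontrolled evolution (600 codons, 60 substitutions):")
for omega in (0.2, 1.0, 5.0):
    ratios = []
    for seed in range(20):
        cds = random_cds(np.random.default_rng(seed), 600)
        derived, _ = evolve_cds_pair(cds, omega, 60, seed=seed)
        ratios.append(kaks.kaks_pair(cds, derived).ratio)
    print(f"  omega {omega:>3.1f}: mean estimated Ka/Ks = "
          f"{np.mean(ratios):.3f}")
# the estimator tracks the generating omega: ~0.2 under purifying
# pressure, ~1 for neutral evolution, well above 1 under positive
# selection
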