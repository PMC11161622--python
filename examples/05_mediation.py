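"""Bootstrap mediation: does a brain pattern carry a cognitive effect?

Tests whether a mediator m explains part of the x -> y relation.  The
indirect effect is the product of the x -> m path (a) and the m -> y
path controlling x (b); its significance comes from a percentile
bootstrap over resampled participants.
"""

import numpy as np

from flowcpm import mediate

rng = np.random.default_rng(0)
n = 500
x = rng.standard_normal(n)                    # e.g. associative ability
m = 0.3 * x + rng.standard_normal(n)          # e.g. a CPM brain score
y = 0.2 * x + 0.4 * m + rng.standard_normal(n)  # e.g. rated novelty

res = mediate(x, m, y, n_boot=1000, seed=1)
print(f"path a (x -> m):          {res.a:+.3f}  (p = {res.p_a:.2g})")
print(f"path b (m -> y | x):      {res.b:+.3f}  (p = {res.p_b:.2g})")
print(f"total effect c:           {res.c:+.3f}")
print(f"direct effect c':         {res.c_prime:+.3f}")
print(f"indirect effect a*b:      {res.indirect:+.3f}")
lo, hi = res.ci[0.95]
print(f"95% bootstrap CI:         [{lo:+.3f}, {hi:+.3f}]"
      f"  -> {'significant' if res.significant(0.95) else 'not significant'}")
print(f"identity c = c' + a*b:    {res.c:.6f} = {res.c_prime + res.indirect:.6f}")
print("\nAn interval excluding zero means the mediator carries a reliable "
      "share of the total effect.")
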