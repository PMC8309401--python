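"""Do related species resemble each other?

Simulates one trait matrix under Brownian motion (full phylogenetic
signal) and one with no signal on the same 14-tip Yule tree, then runs
the signal statistics on both: multivariate Kmult (about 1 under BM),
univariate Blomberg's K, Abouheif's Cmean permutation test, and the
maximum-likelihood Pagel's lambda with its likelihood-ratio p.
"""

from floracues.phylosignal import (
    blomberg_k,
    cmean_test,
    kmult,
    pagel_lambda_fit,
)
from floracues.synth import gen_yule_tree, sim_traits

tree = gen_yule_tree(14, seed=1)

for label, lam in (("Brownian motion (lambda=1)", 1.0),
                   ("no signal (lambda=0)", 0.0)):
    X = sim_traits(tree, p=5, lam=lam, seed=11)
    x = X.iloc[:, 0].to_numpy()
    km = kmult(X.to_numpy(), tree, n_perm=999, seed=2)
    cm = cmean_test(x, tree, n_perm=999, seed=2)
    lf = pagel_lambda_fit(x, tree)
    print(f"\n{label}:")
    print(f"  Kmult  = {km.value:.2f}, p = {km.p:.3f}")
    print(f"  K      = {blomberg_k(x, tree):.2f} (first trait)")
    print(f"  Cmean  = {cm.value:.2f}, p = {cm.p:.3f}")
    print(f"  lambda = {lf.value:.2f}, p = {lf.p:.3g} "
          f"(lnL {lf.nuisance['lnL_hat']:.2f} vs lnL0 "
          f"{lf.nuisance['lnL_0']:.2f})")

print("\nUnder BM the statistics sit near their signal values (Kmult ~ 1, "
      "lambda ~ 1, small p); without signal they collapse toward 0 with "
      "large p.")
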