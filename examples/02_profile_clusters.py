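"""Profile clusters against covariates with chi-square and residuals.

Recomputes the reference cross-tabulation statistics of the 2019
Colombian substance-use survey cluster analysis from their published
counts: chi-square tests of independence, Haberman adjusted residuals,
and per-cluster prevalence of substance use.
"""

import numpy as np

import caedec as cd
from caedec import reference as ref
from caedec.profiling import format_p

for var in ("gender", "ses", "contributes"):
    t = ref.contingency(var)
    res = cd.chi_square_test(t)
    print(f"{var:12s} chi2 = {res.statistic:8.2f}  df = {res.df}  "
          f"p {format_p(res.p_value)}")
    resid = cd.adjusted_residuals(t)
    for row, r in zip(t.row_labels, np.round(resid, 2)):
        print(f"    {row:8s} residuals {r.tolist()}")
# |residual| > 2 marks a category over-/under-represented in a cluster
# relative to independence (approximately N(0,1) under the null).

labels = np.repeat([0, 1, 2], ref.CLUSTER_SIZES)
outcome = np.concatenate([
    np.r_[np.ones(p), np.zeros(s - p)]
    for s, p in zip(ref.CLUSTER_SIZES, ref.PREVALENCE_POSITIVES)
]).astype(int)
print(cd.prevalence_by_cluster(labels, outcome).to_string(index=False))
# percent = share of cluster members who report substance use.
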