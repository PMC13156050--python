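"""Group tests computed from printed summary statistics alone.

Given per-group (mean, SD, n) and a 2x2 sex table — the numbers a paper
prints — reproduce the test statistics.  The variance-ratio rule decides
between the pooled and Welch t per variable.
"""
from callothick.demographics import GroupSummary, chi_square_counts, two_sample_t

pairs = {
    "age":       (GroupSummary(20.34, 6.93, 151), GroupSummary(23.71, 5.95, 278)),
    "education": (GroupSummary(11.27, 2.81, 151), GroupSummary(15.09, 3.17, 278)),
    "tiv":       (GroupSummary(1449.59, 127.23, 151), GroupSummary(1446.47, 123.79, 278)),
}
for name, (a, b) in pairs.items():
    r = two_sample_t(a, b)
    print(f"{name:10s} {r.test:6s} t = {r.statistic:7.2f}  df = {r.df:6.1f}  p = {r.p:.3g}")
chi = chi_square_counts([[59, 92], [92, 186]])
print(f"{'sex':10s} {'chi2':6s} X2 = {chi.statistic:.3f}  p = {chi.p:.3f}")
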