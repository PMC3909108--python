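"""The chance-agreement model behind the redundancy criterion.

Under a null where each spectrum independently favors one of n candidate
sites uniformly at random, k agreeing spectra are all wrong with probability
(1/n)^k.  The table shows why 7 agreeing spectra over two sites clear the
99% confidence level, which is why redundancy >= 7 passes without a dCn gate.
"""

from phosloc import chance_agreement_probability

print("sites  agreeing-spectra  P(correct)")
for n_sites in (2, 3):
    for k in (1, 4, 6, 7, 10):
        p = chance_agreement_probability(n_sites, k)
        mark = "  <-- crosses 99%" if n_sites == 2 and k == 7 else ""
        print(f"{n_sites:>5}  {k:>16}  {p:.7f}{mark}")
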