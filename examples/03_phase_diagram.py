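"""Steady-state regimes of the clustering model over the two association
ratios, and the effect of the detailed-balance restriction.

Each cell integrates the clustering model to steady state and labels it by
where most receptor mass sits: unclustered (u), dimers (d), or full
clustering (f).  Imposing detailed balance (k2/k_m2 = k1/k_m1) removes the
dimer regime entirely.

A 6x6 grid keeps this example quick while still hitting all three regimes;
the dimer band is narrow (monomer ratio around 2-5 with a small dimer
ratio), so coarse grids can miss it if the sample points fall outside the
band.  The full-resolution figure uses a 20x20 grid.
"""

import numpy as np

from aggkin import phase_diagram

r = np.logspace(-3, 3, 6)


def render(pd):
    print("      k2/k_m2 ->")
    for a in range(len(pd.ratio_monomer) - 1, -1, -1):
        row = "".join(
            {"unclustered": "u", "dimers": "d", "full_clustering": "f"}[
                pd.labels[a, b].value]
            for b in range(len(pd.ratio_dimer))
        )
        print(f"  {pd.ratio_monomer[a]:8.2e}  {row}")


print("free rates (k_m1 = k_m2 = 1, N = 15):")
pd = phase_diagram(r, r, N=15)
render(pd)
print("labels:", sorted(l.value for l in pd.label_set()))

print("\nwith detailed balance imposed:")
pd_db = phase_diagram(r, r, N=15, detailed_balance=True)
render(pd_db)
print("labels:", sorted(l.value for l in pd_db.label_set()))
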