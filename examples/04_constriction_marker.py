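"""Tube squeezing into a constriction; local inextensibility marker.

A quasi-static (rho = 0) Poiseuille inflow pushes an elongated vesicle
(reduced area 0.351) toward a channel narrowing.  A marker field Psi,
initialised to 1 and transported with the membrane, measures local length
change: with linear interface interpolation (ell = 1) it stays within a
fraction of a percent of 1 -- the scheme preserves local membrane length --
while ell = 2 lets the vertices drift along the contour.

Scaled down (K_Gamma = 33, adapt_{4,2}, T = 0.4) this takes ~1-2 minutes.
"""

from fm2d import Simulation

for ell in (1, 2):
    sim = Simulation("constriction", n_fine=16, n_coarse=4, tau=1e-3,
                     k_gamma=33, ell=ell)
    for _ in range(400):
        sim.step()
    r = sim.state.history[-1]
    ra = max(rec["r_a"] for rec in sim.state.history)
    print(f"ell={ell}: Psi in [{r['psi_min']:.4f}, {r['psi_max']:.4f}]  "
          f"max r_a {ra:.4f}")

print("\nell=1 keeps Psi pinned near 1 (local length preserved) and the")
print("polygon nearly equidistributed; ell=2 visibly does not.")
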