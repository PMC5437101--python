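"""The best-fit maize history: scaled units, physical units, timeline.

Builds the published double-bottleneck history, shows how scaled
diffusion units (nu, tau, M) convert to individuals and years via
theta = 4*Na*mu*L, and prints the epoch structure.
"""

from tempdiff import build_timeline, maize_split5_bestfit, to_physical, to_scaled

phys = maize_split5_bestfit()
print(f"ancestral size Na      : {phys.Na:,.0f} individuals")
print(f"theta = 4*Na*mu*L      : {phys.theta:,.1f}")
print(f"bottleneck             : {phys.sizes['nu_b']:.0f} individuals "
      f"for {phys.durations['tau1']:.0f} generations")
print(f"TS / NSS at the split  : {phys.sizes['nu1']:,.0f} / "
      f"{phys.sizes['nu2']:,.0f} individuals "
      f"(total {phys.sizes['nu1'] + phys.sizes['nu2']:,.0f})")
print(f"divergence stage       : {phys.durations['tau2']:.0f} years")
print(f"shrinking stage        : {phys.durations['tau3']:.0f} years, "
      f"declines {100 * (1 - phys.sizes['nu1e'] / phys.sizes['nu1']):.0f}% (TS) "
      f"and {100 * (1 - phys.sizes['nu2e'] / phys.sizes['nu2']):.0f}% (NSS)")
print(f"split age              : "
      f"{phys.durations['tau2'] + phys.durations['tau3']:.0f} years ago")
for name in ("m1", "m2"):
    print(f"migration {name}           : M = {phys.migration[name]:.2e} "
          f"(m = {phys.migrant_proportion(name):.2e} per generation)")

scaled = to_scaled(phys)
print("\nscaled parameters:", {k: round(v, 6) for k, v in scaled.params.items()})
assert to_physical(scaled, phys.mu, phys.L).Na == phys.Na  # exact round trip

print("\ntimeline (past -> present):")
for epoch in build_timeline(scaled).epochs:
    sizes = ", ".join(f"{s.kind} {s.start:.4g}->{s.end:.4g}"
                      for s in epoch.sizes)
    print(f"  duration {epoch.duration:.6g}  demes [{sizes}]")
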