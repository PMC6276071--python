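"""The free-energy ledger of an asymmetric carrier.

A tenfold affinity difference between the two faces costs
RT ln(10) per mole of ligand moved between the sites.  A detailed-
balanced carrier 'pays' for it with a tenfold asymmetry in empty-
carrier rates, worth exactly -RT ln(10).  But at equilibrium the
chemical potential of every mobile component must be equal in all
connected phases, so the concentration asymmetry of the empty carrier
must be offset by a reciprocal activity-coefficient asymmetry -- it
stores no free energy and cannot drive anything."""

from portersim import (
    EnergyContext,
    ThermoState,
    activity_coefficient_ratio,
    chemical_potential,
    empty_rate_ratio_from_vacant_ratio,
    rate_asymmetry_energy,
    site_energy_gap,
    vacant_ratio_from_kd,
)

ctx = EnergyContext(303.15)  # 30 C

gap = site_energy_gap(kd_in=30.0, kd_out=3.0, ctx=ctx)
print(f"site affinity gap  RT ln(KD_in/KD_out)      = {gap:+.3f} kJ/mol")

vacant = vacant_ratio_from_kd(30.0, 3.0)
rates = empty_rate_ratio_from_vacant_ratio(vacant)
print(f"forced vacant-site ratio C_in/C_out          = {vacant:.1f}")
print(f"required empty-rate ratio k_oi/k_io          = {rates:.1f}")

asym = rate_asymmetry_energy(rates, 1.0, ctx)
print(f"rate-asymmetry energy -RT ln(k_oi/k_io)      = {asym:+.3f} kJ/mol")
print(f"ledger total (the 'free' transport cycle)    = {gap + asym:+.3f} kJ/mol")

gamma = activity_coefficient_ratio(1.0, vacant)
print(f"\nactivity-coefficient ratio gamma_in/gamma_out = {gamma:.2f}")
mu_out = chemical_potential(ThermoState(0.0, 0.01, 1.0), ctx)
mu_in = chemical_potential(ThermoState(0.0, 0.10, gamma), ctx)
print(f"chemical potentials: out {mu_out:.6f}, in {mu_in:.6f} kJ/mol "
      f"(difference {mu_in - mu_out:.2e})")

print("""
The two energies cancel to zero -- that is the carrier scheme's
bookkeeping.  The last lines show why the cancellation cannot be a real
energy source: equal activities mean equal chemical potentials, so the
asymmetric vacant-carrier distribution is thermodynamically inert.""")
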