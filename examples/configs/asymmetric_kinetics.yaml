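# Zero-trans and exchange kinetics of the default asymmetric carrier,
# with the detailed-balance / equilibrium audit.
#   portersim run --config examples/configs/asymmetric_kinetics.yaml --out out
model:
  type: asymmetric
protocols:
  - type: zero_trans_influx
  - type: zero_trans_efflux
  - type: equilibrium_exchange_influx
audit:
  bath_conc: 5.0
seed: 0
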