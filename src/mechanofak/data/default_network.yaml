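# Default force-gated FAK -> Src/SHC/Grb2/SOS -> Ras signalling network.
#
# Order-of-magnitude constants in the range used by published receptor ->
# Ras mass-action network models: association constants ~1e6 /M/s
# (= 1e-3 /nM/s), dissociation ~0.1 /s, catalytic turnover a few per
# second.  Every constant here is editable; an alternative reaction scheme
# can be dropped in through the same file format.
#
# Units: concentrations nM, time s, bimolecular constants 1/(nM s).

species:
  FAK_closed: 100.0     # autoinhibited FAK
  FAK_open: 0.0         # force-activated FAK (interface open)
  Src: 100.0
  FAK_Src: 0.0          # active FAK-Src complex (kinase-competent)
  SHC: 100.0
  SHC_p: 0.0            # phosphorylated SHC
  Grb2: 100.0
  SOS: 50.0
  SHC_Grb2: 0.0
  SHC_Grb2_SOS: 0.0
  E: 0.0                # assembled exchange enzyme FAK-Src-SHCp-Grb2-SOS
  Ras_GDP: 500.0
  E_Ras: 0.0            # enzyme-substrate complex
  Ras_GTP: 0.0

rates:
  k_close: 1.0e-5       # 1/s, re-docking of the autoinhibitory interface
  ka_src: 1.0e-3        # 1/(nM s)
  kd_src: 0.1           # 1/s
  k_phos: 1.0e-4        # 1/(nM s), FAK_Src-catalysed SHC phosphorylation
  k_dephos: 1.0e-3      # 1/s, background phosphatase activity
  ka_grb2: 1.0e-3
  kd_grb2: 0.1
  ka_sos: 1.0e-3
  kd_sos: 0.1
  ka_e: 1.0e-3
  kd_e: 0.1
  kon_ras: 1.0e-3       # 1/(nM s)
  koff_ras: 1.0         # 1/s
  kcat: 5.0             # 1/s, GDP -> GTP exchange turnover

# The three landscape parameter sets correspond to three constrained
# rupture-spectrum fits from the good-fit (RMSD <= 15 pN) region; all have
# a spontaneous opening rate k0 <= 1e-3 1/s.  Set 1 is the headline fit.
landscape_sets:
  1: {deltaG_kT: 28.5, xb_nm: 0.86, D_nm2_per_s: 6.6e+6, temperature_K: 300.0}
  2: {deltaG_kT: 26.5, xb_nm: 0.78, D_nm2_per_s: 1.0e+6, temperature_K: 300.0}
  3: {deltaG_kT: 35.0, xb_nm: 1.00, D_nm2_per_s: 5.0e+7, temperature_K: 300.0}
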