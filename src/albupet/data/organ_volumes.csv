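# Human per-organ volumes (mL) and mass fractions used for theoretical tissue-to-plasma bounds.
# Typed in from standard PBPK volume compilations for a ~75 kg adult male (Shah & Betts 2012,
# J Pharmacokinet Pharmacodyn 39:67-86, and ICRP reference-man values for organs absent there).
# Brain plasma volume is calibrated so V_P/V_org = 0.025, the measured vascular-confinement
# plateau of albumin-bound tracers in brain.  Density is assumed 1 g/mL throughout.
organ,V_org_mL,V_P_mL,V_I_mL,mass_fraction
brain,1450.0,36.25,261.0,0.01933
lung,1000.0,145.0,300.0,0.01333
liver,1690.0,183.0,429.0,0.02253
spleen,221.0,26.8,39.8,0.00295
kidney,332.0,18.2,49.8,0.00443
heart,341.0,13.1,48.8,0.00455
muscle,30078.0,662.0,3910.0,0.40104
pancreas,104.0,5.7,18.0,0.00139
testis,35.9,0.9,5.2,0.00048
bone_marrow,1170.0,53.8,230.0,0.01560
parotid_gland,50.0,2.5,10.0,0.00067
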