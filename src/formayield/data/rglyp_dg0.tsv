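# Reductive glycine pathway, formate -> pyruvate.
# Transformed standard Gibbs energies at pH 7.5, I = 0.25 M, [Mg2+] = 1 mM, 298.15 K.
# RECONSTRUCTED values on the literature scale for the component-contribution
# framework; this package does not implement the estimator itself.  Water and
# protons are folded into dG'0 (activity 1 / fixed pH convention).
reaction_id	equation	dg0_prime_kj_mol	ph	ionic_strength_M	mg_M	provenance
FtfL	formate + thf + atp -> 10fthf + adp + pi	-8.0	7.5	0.25	0.001	reconstructed
FchA	10fthf + h -> methf + h2o	3.5	7.5	0.25	0.001	reconstructed
MtdA	methf + nadph -> mlthf + nadp	-5.0	7.5	0.25	0.001	reconstructed
GCS	mlthf + co2 + nh3 + nadh -> gly + thf + nad	14.0	7.5	0.25	0.001	reconstructed
GlyA	gly + mlthf + h2o -> ser + thf	5.0	7.5	0.25	0.001	reconstructed
SdaA	ser -> pyr + nh3	-35.0	7.5	0.25	0.001	reconstructed
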