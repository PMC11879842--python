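# Calvin-Benson-Bassham route, 3 CO2 -> pyruvate (formate supplies only energy).
# Transformed standard Gibbs energies at pH 7.5, I = 0.25 M, [Mg2+] = 1 mM, 298.15 K.
# RECONSTRUCTED values on the literature scale; GAPDH is encoded with the NAD
# couple.  PPREGEN lumps triose-phosphate recycling (TPI/aldolase/FBPase/
# transketolase/SBPase) into one step; PYKL lumps 3PG -> pyruvate
# (PGM/enolase/pyruvate kinase).
reaction_id	equation	dg0_prime_kj_mol	ph	ionic_strength_M	mg_M	provenance
Prk	ru5p + atp -> rubp + adp + h	-21.0	7.5	0.25	0.001	reconstructed
RBPC	rubp + co2 + h2o -> 2 3pg + 2 h	-29.0	7.5	0.25	0.001	reconstructed
PGK	3pg + atp -> 13dpg + adp	19.0	7.5	0.25	0.001	reconstructed
GAPDH	13dpg + nadh + h -> g3p + nad + pi	-7.5	7.5	0.25	0.001	reconstructed
PPREGEN	5 g3p + 2 h2o -> 3 ru5p + 2 pi	-25.0	7.5	0.25	0.001	reconstructed
PYKL	3pg + adp + h -> pyr + atp + h2o	-24.0	7.5	0.25	0.001	reconstructed
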