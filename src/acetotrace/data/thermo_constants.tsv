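species	dg0_prime_kj_mol	conditions_note
ethanol	-181.75	aqueous, standard transformed, pH 7, 298.15 K, I ~ 0
acetate	-369.41	aqueous anion, standard transformed, pH 7, 298.15 K, I ~ 0
acetaldehyde	-139.90	aqueous, standard transformed, pH 7, 298.15 K, I ~ 0
H2O	-237.18	liquid water; activity conventionally 1
H+	-39.87	proton at pH 7 (RT ln 1e-7 convention folded into the species entry)
H2	0.00	dissolved/gas at 1 bar reference
glucose	-917.22	aqueous, standard transformed, pH 7, 298.15 K, I ~ 0
glycerol	-488.52	aqueous, standard transformed, pH 7, 298.15 K, I ~ 0
CO2	-394.36	gas at 1 bar reference
HCO3-	-586.85	aqueous anion, standard transformed, pH 7, 298.15 K, I ~ 0
CH4	-50.75	gas at 1 bar reference
NAD+	0.00	redox-pair convention: NAD+/NADH pair carries -62.0 via NADH entry
NADH	-62.00	relative to NAD+ at pH 7 (E0' = -0.32 V, 2 e-)
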