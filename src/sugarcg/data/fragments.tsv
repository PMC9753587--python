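# sugarcg fragment/bead table, version 1
# One record per fragment kind. "status" records the provenance of the bead
# type label: "text" = fixed by the written parametrization rules;
# "unverified" = the package's own Martini 3 label choice for fragments whose
# label is defined only graphically in the source model.
name	size	bead_type	example_atoms	status	note
diol	small	SP4r	C3,O3,C4,O4	unverified	vicinal diol on two ring carbons; inositol is three of these and all its beads share this type
hemiacetal	small	SP1r	C1,O1,C2,O2	text	anomeric carbon with its hydroxyl plus adjacent CHOH; the 1-1..1-4 glycosidic bead type is taken over from it
ring_ether	small	SP1r	C5,C6,O6,O5	unverified	ring oxygen with exocyclic CH2OH
ring_ether_tiny	tiny	TP1	C5,O5	unverified	2:1 ring-ether fragment left after isolating a substituent (xylose, uronic acids)
ring_ether_deoxy	small	SN4	C5,C6,O5	unverified	ring oxygen with exocyclic methyl (6-deoxy sugars rhamnose/fucose)
hydroxyl	tiny	TP1	C3,O3	unverified	single CHOH unit in 2:1 mapping
ring_monoalcohol	small	SP1	C3,C4,O4,C5	unverified	4:1 ring fragment carrying a single hydroxyl (sialic acid ring)
acid	small	SP2	C6,O61,O62	unverified	carboxylic acid substituent kept together as its own small bead
acid_anomeric	regular	P2	C2,O2,C1,O1A,O1B	text	carboxylic acid grouped with the anomeric carbon fragment into one regular bead; standard Martini 3 carboxylic acid type
acetamide	small	SP2a	N5,C10,O10,C11	unverified	N-acetyl substituent kept together
glyc_11	small	SP1r	-	text	glycosidic 1-1 fragment
glyc_12	small	SP1r	-	text	glycosidic 1-2 fragment
glyc_13	small	SP1r	-	text	glycosidic 1-3 fragment
glyc_14	small	SP1r	-	text	glycosidic 1-4 fragment
glyc_15	small	SN6r	-	text	glycosidic 1-5 fragment; hemiacetal with one OH replaced by an ether, one level weaker self-interaction
glyc_16	small	SN6r	-	text	glycosidic 1-6 fragment; same rationale as glyc_15
glyc_neu5ac_acid	regular	P2	-	text	sialic-acid glycosidic fragment with the carboxylic acid grouped in; standard Martini 3 carboxylic acid type
virtual_site	tiny	TC4	-	text	massless ring-centroid interaction site, identical for all monosaccharides
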