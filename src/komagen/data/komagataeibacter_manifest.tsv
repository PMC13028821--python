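accession	species	strain	size_bp	source	excluded_clonal
GCF_000182745.2	K. medellinensis	NBRC 3288	3513191	Vinegar	false
GCF_002009295.1	K. nataicola	RZS01	3760301	Rotten apple	false
GCF_002173515.1	K. europaeus	SRCM101446	3797909	NA	false
GCF_003546645.1	K. saccharivorans	CV1	3768311	Vinegar	false
GCF_004006375.1	K. xylinus	DSM 2325	3727795	NA	false
GCF_004348195.1	K. saccharivorans	JH1	3727857	Fruit fly	false
GCF_009834365.1	K. xylinus	CGMCC 17276	3983026	Green jujube	false
GCF_019052775.1	K. oboediens	SI3053	3666777	Apple cider vinegar production	false
GCF_029229465.1	K. oboediens	NCIB 8034	4059958	Kombucha tea culture	false
GCF_029229505.1	K. nataicola	DS12	3916688	Kombucha tea culture	false
GCF_032075085.1	K. nataicola	FWP-2023	3767936	NA	false
GCF_034063025.1	K. rhaeticus	CGMCC 2955	3563316	Vinegar	false
GCF_040581405.1	K. sucrofermentans	JCM 9730	3437745	Black cherry	false
GCF_043995075.1	K. diospyri	MI2	3885945	Ripen Sapodilla fruit	false
GCF_047795655.1	K. sucrofermentans	SMEG01	3442337	Apple	false
GCF_049202445.1	K. intermedius	SLAM-NK6B	3661158	Kombucha	false
GCF_052445895.1	K. intermedius	FM883	4235196	Kombucha tea	false
GCF_900086575.1	K. rhaeticus	iGEM	3867346	Kombucha tea Scoby	false
GCF_011611525.1	K. rhaeticus	ENS 9a1a	0	NA	true
GCF_014725815.1	K. rhaeticus	ENS9b	0	NA	true
GCF_040581375.1	K. sucrofermentans	JML KO23	0	NA	true
GCF_040581385.1	K. sucrofermentans	JML 2321	0	NA	true
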