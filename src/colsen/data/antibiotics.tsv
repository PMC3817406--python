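name	abbreviation	moa_class	cidality	gradient_flag
Ampicillin	AMP	Cell wall	bactericidal	1
Piperacillin	PIP	Cell wall	bactericidal	0
Cefoxitin	FOX	Cell wall	bactericidal	1
Fosfomycin	FOS	Cell wall	bactericidal	0
Lomefloxacin	LOM	Gyrase	bactericidal	0
Ciprofloxacin	CPR	Gyrase	bactericidal	1
Nalidixic acid	NAL	Gyrase	bactericidal	1
Fosmidomycin	FSM	Lipid	bactericidal	0
Nitrofurantoin	NIT	Multiple mechanisms	bactericidal	1
Amikacin	AMK	Aminoglycoside	bactericidal	0
Gentamicin	GEN	Aminoglycoside	bactericidal	0
Kanamycin	KAN	Aminoglycoside	bactericidal	1
Tobramycin	TOB	Aminoglycoside	bactericidal	1
Streptomycin	STR	Aminoglycoside	bactericidal	0
Tetracycline	TET	Protein synthesis, 30S	bacteriostatic	1
Doxycycline	DOX	Protein synthesis, 30S	bacteriostatic	1
Chloramphenicol	CHL	Protein synthesis, 50S	bacteriostatic	1
Erythromycin	ERY	Protein synthesis, 50S	bacteriostatic	1
Fusidic acid	FUS	Protein synthesis, 50S	bacteriostatic	0
Sulfamonomethoxine	SLF	Folic acid biosynthesis	bacteriostatic	0
Trimethoprim	TRM	Folic acid biosynthesis	bacteriostatic	1
Mupirocin	MUP	Gram positive	NA	0
Cycloserine	CYC	Gram positive	NA	0
Vancomycin	VAN	Gram positive	NA	0
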