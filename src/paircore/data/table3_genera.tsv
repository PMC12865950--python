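taxon	rank	material	platform	engine	direction	lefse_identified	sensitivity_passed	education_covariate_passed
Anaeroglobus	genus	saliva	FL	LIMMA	patient	TRUE		TRUE
Anaeroglobus	genus	saliva	SR	LIMMA	patient	TRUE		TRUE
Anaeroglobus	genus	saliva	FL	ALDEX	patient	TRUE		TRUE
Anaeroglobus	genus	saliva	SR	ALDEX	patient	TRUE		TRUE
Anaeroglobus	genus	saliva	SR	ANCOM	patient	TRUE	TRUE	FALSE
Lactobacillus	genus	saliva	SR	LIMMA	patient	FALSE		TRUE
Lactobacillus	genus	saliva	WGS	ANCOM	patient	FALSE	TRUE	TRUE
Lactobacillus	genus	saliva	FL	ANCOM	patient	FALSE	TRUE	TRUE
Lactobacillus	genus	saliva	SR	ANCOM	patient	FALSE	TRUE
Lactobacillus	genus	supragingival	FL	ANCOM	patient	FALSE	TRUE	TRUE
Olsenella	genus	saliva	SR	LIMMA	patient	TRUE		TRUE
Olsenella	genus	saliva	SR	ALDEX	patient	TRUE		TRUE
Olsenella	genus	saliva	WGS	ANCOM	patient	FALSE	TRUE	TRUE
Olsenella	genus	saliva	SR	ANCOM	patient	TRUE	TRUE	FALSE
Dialister	genus	saliva	SR	LIMMA	patient	TRUE		FALSE
Dialister	genus	saliva	WGS	ANCOM	patient	FALSE	TRUE	FALSE
Dialister	genus	saliva	SR	ANCOM	patient	TRUE	TRUE	FALSE
Dialister	genus	supragingival	FL	ANCOM	patient	FALSE	FALSE	FALSE
Schwartzia	genus	saliva	SR	LIMMA	patient	TRUE		FALSE
Schwartzia	genus	saliva	FL	ANCOM	patient	FALSE	TRUE	FALSE
Schwartzia	genus	saliva	SR	ANCOM	patient	TRUE	TRUE	FALSE
Schwartzia	genus	supragingival	FL	ANCOM	patient	TRUE	TRUE	FALSE
Schwartzia	genus	supragingival	SR	ANCOM	patient	TRUE	TRUE	FALSE
Streptococcus	genus	saliva	WGS	ANCOM	control	FALSE	FALSE	FALSE
Streptococcus	genus	saliva	FL	ANCOM	control	FALSE	FALSE	FALSE
Streptococcus	genus	saliva	SR	ANCOM	control	FALSE	FALSE	FALSE
Veillonella	genus	saliva	WGS	ANCOM	control	FALSE	FALSE	FALSE
Veillonella	genus	saliva	FL	ANCOM	control	FALSE	FALSE	FALSE
Veillonella	genus	saliva	SR	ANCOM	control	FALSE	FALSE	FALSE
Lachnoanaerobaculum	genus	saliva	WGS	ANCOM	control	FALSE	TRUE	FALSE
Lachnoanaerobaculum	genus	saliva	FL	ANCOM	control	FALSE	TRUE	FALSE
Lachnoanaerobaculum	genus	saliva	SR	ANCOM	control	FALSE	TRUE	FALSE
Lachnoanaerobaculum	genus	supragingival	FL	ANCOM	control	FALSE	TRUE	FALSE
Lachnoanaerobaculum	genus	supragingival	SR	ANCOM	control	TRUE	TRUE	FALSE
Oribacterium	genus	saliva	WGS	ANCOM	control	FALSE	TRUE	FALSE
Oribacterium	genus	saliva	FL	ANCOM	control	FALSE	TRUE	FALSE
Oribacterium	genus	saliva	SR	ANCOM	control	FALSE	TRUE	FALSE
Schaalia	genus	saliva	WGS	ANCOM	control	FALSE	FALSE	FALSE
Schaalia	genus	saliva	FL	ANCOM	control	FALSE	TRUE	FALSE
Schaalia	genus	saliva	SR	ANCOM	control	FALSE	FALSE	FALSE
Schaalia	genus	supragingival	SR	ANCOM	control	FALSE	FALSE	FALSE
Campylobacter	genus	saliva	WGS	ANCOM	control	FALSE	TRUE	FALSE
Campylobacter	genus	saliva	SR	ANCOM	control	FALSE	FALSE	FALSE
Campylobacter	genus	supragingival	SR	ANCOM	control	FALSE	TRUE	FALSE
Prevotella	genus	saliva	WGS	ANCOM	control	FALSE	FALSE	FALSE
Prevotella	genus	saliva	FL	ANCOM	control	FALSE	TRUE	FALSE
Prevotella	genus	saliva	SR	ANCOM	control	FALSE	FALSE	FALSE
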