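taxon	rank	material	platform	engine	direction	lefse_identified	sensitivity_passed	education_covariate_passed
Prevotella nigrescens	species	saliva	WGS	LIMMA	patient	FALSE		TRUE
Prevotella nigrescens	species	saliva	FL	LIMMA	patient	TRUE		TRUE
Prevotella nigrescens	species	saliva	SR	LIMMA	patient	TRUE		TRUE
Prevotella nigrescens	species	saliva	FL	ALDEX	patient	TRUE		TRUE
Prevotella nigrescens	species	saliva	SR	ALDEX	patient	TRUE		TRUE
Prevotella nigrescens	species	saliva	WGS	ANCOM	patient	FALSE	TRUE	TRUE
Prevotella nigrescens	species	saliva	FL	ANCOM	patient	TRUE	TRUE	TRUE
Prevotella nigrescens	species	saliva	SR	ANCOM	patient	TRUE	TRUE	TRUE
Prevotella nigrescens	species	supragingival	FL	ANCOM	patient	FALSE	TRUE	TRUE
Prevotella nigrescens	species	supragingival	SR	ANCOM	patient	TRUE	FALSE	FALSE
Streptococcus sp. oral taxon 431	species	saliva	WGS	LIMMA	control	FALSE		FALSE
Streptococcus sp. oral taxon 431	species	saliva	FL	LIMMA	control	FALSE		FALSE
Streptococcus sp. oral taxon 431	species	saliva	WGS	ANCOM	control	FALSE	FALSE	FALSE
Streptococcus sp. oral taxon 431	species	saliva	FL	ANCOM	control	FALSE	FALSE	FALSE
Prevotella maculosa	species	saliva	FL	LIMMA	patient	TRUE		TRUE
Prevotella maculosa	species	saliva	SR	LIMMA	patient	TRUE		TRUE
Prevotella maculosa	species	saliva	FL	ALDEX	patient	TRUE		TRUE
Prevotella maculosa	species	saliva	SR	ALDEX	patient	TRUE		TRUE
Prevotella maculosa	species	saliva	WGS	ANCOM	patient	FALSE	TRUE	TRUE
Prevotella maculosa	species	saliva	FL	ANCOM	patient	TRUE	TRUE	TRUE
Prevotella maculosa	species	saliva	SR	ANCOM	patient	TRUE	TRUE	TRUE
Streptococcus anginosus	species	saliva	FL	LIMMA	patient	TRUE		TRUE
Streptococcus anginosus	species	saliva	SR	LIMMA	patient	TRUE		TRUE
Streptococcus anginosus	species	saliva	FL	ALDEX	patient	TRUE		TRUE
Streptococcus anginosus	species	saliva	SR	ALDEX	patient	TRUE		TRUE
Streptococcus anginosus	species	saliva	WGS	ANCOM	patient	FALSE	TRUE	FALSE
Streptococcus anginosus	species	saliva	FL	ANCOM	patient	TRUE	TRUE	FALSE
Streptococcus anginosus	species	saliva	SR	ANCOM	patient	TRUE	TRUE	TRUE
Streptococcus anginosus	species	supragingival	FL	ANCOM	patient	FALSE	TRUE	TRUE
Streptococcus anginosus	species	supragingival	SR	ANCOM	patient	FALSE	TRUE	FALSE
Anaeroglobus geminatus	species	saliva	FL	LIMMA	patient	TRUE		TRUE
Anaeroglobus geminatus	species	saliva	SR	LIMMA	patient	TRUE		TRUE
Anaeroglobus geminatus	species	saliva	FL	ALDEX	patient	TRUE		TRUE
Anaeroglobus geminatus	species	saliva	SR	ALDEX	patient	TRUE		TRUE
Anaeroglobus geminatus	species	saliva	SR	ANCOM	patient	TRUE	TRUE	TRUE
Leptotrichia hofstadii	species	saliva	FL	LIMMA	patient	TRUE		TRUE
Leptotrichia hofstadii	species	saliva	FL	ALDEX	patient	TRUE		TRUE
Leptotrichia hofstadii	species	saliva	WGS	ANCOM	patient	FALSE	TRUE	FALSE
Veillonella dispar	species	saliva	FL	LIMMA	control	TRUE		TRUE
Veillonella dispar	species	saliva	WGS	ANCOM	control	TRUE	FALSE	TRUE
Veillonella dispar	species	saliva	FL	ANCOM	control	TRUE	TRUE	TRUE
Veillonella dispar	species	saliva	SR	ANCOM	control	FALSE	TRUE	FALSE
Selenomonas infelix	species	saliva	FL	LIMMA	patient	TRUE		TRUE
Selenomonas infelix	species	saliva	FL	ALDEX	patient	TRUE		TRUE
Selenomonas infelix	species	saliva	FL	ANCOM	patient	TRUE	TRUE	FALSE
Selenomonas infelix	species	saliva	SR	ANCOM	patient	TRUE	TRUE	TRUE
Lachnoanaerobaculum orale	species	saliva	FL	LIMMA	control	FALSE		FALSE
Lachnoanaerobaculum orale	species	saliva	FL	ANCOM	control	FALSE	TRUE	FALSE
Lachnoanaerobaculum orale	species	saliva	SR	ANCOM	control	FALSE	TRUE	FALSE
Streptococcus parasanguinis	species	saliva	FL	LIMMA	control	FALSE		TRUE
Streptococcus parasanguinis	species	saliva	SR	LIMMA	control	FALSE		TRUE
Streptococcus parasanguinis	species	saliva	WGS	ANCOM	control	TRUE	FALSE	TRUE
Streptococcus parasanguinis	species	saliva	FL	ANCOM	control	FALSE	FALSE	TRUE
Streptococcus parasanguinis	species	saliva	SR	ANCOM	control	FALSE	FALSE	FALSE
Streptococcus parasanguinis	species	supragingival	FL	ANCOM	control	FALSE	TRUE	FALSE
Streptococcus sp. LPB0220	species	saliva	FL	LIMMA	control	TRUE		TRUE
Streptococcus sp. LPB0220	species	saliva	WGS	ANCOM	control	FALSE	FALSE	FALSE
Streptococcus sp. LPB0220	species	saliva	FL	ANCOM	control	TRUE	TRUE	TRUE
Streptococcus sp. LPB0220	species	saliva	SR	ANCOM	control	FALSE	TRUE	FALSE
Selenomonas sp. oral taxon 920	species	saliva	SR	LIMMA	patient	TRUE		TRUE
Selenomonas sp. oral taxon 920	species	saliva	FL	ALDEX	patient	TRUE		TRUE
Selenomonas sp. oral taxon 920	species	saliva	SR	ALDEX	patient	TRUE		TRUE
Selenomonas sp. oral taxon 920	species	saliva	WGS	ANCOM	patient	FALSE	TRUE	TRUE
Selenomonas sp. oral taxon 920	species	saliva	FL	ANCOM	patient	TRUE	TRUE	FALSE
Selenomonas sp. oral taxon 920	species	saliva	SR	ANCOM	patient	TRUE	TRUE	TRUE
Pseudopropionibacterium propionicum	species	saliva	SR	LIMMA	patient	FALSE		FALSE
Pseudopropionibacterium propionicum	species	saliva	WGS	ANCOM	patient	FALSE	TRUE	FALSE
Pseudopropionibacterium propionicum	species	saliva	SR	ANCOM	patient	FALSE	FALSE	FALSE
Pseudopropionibacterium propionicum	species	supragingival	FL	ANCOM	patient	FALSE	TRUE	FALSE
Prevotella melaninogenica	species	saliva	WGS	ANCOM	control	FALSE	FALSE	FALSE
Prevotella melaninogenica	species	saliva	FL	ANCOM	control	FALSE	TRUE	FALSE
Prevotella melaninogenica	species	saliva	SR	ANCOM	control	FALSE	TRUE	FALSE
Leptotrichia buccalis	species	saliva	WGS	ANCOM	patient	FALSE	TRUE	FALSE
Leptotrichia buccalis	species	saliva	FL	ANCOM	patient	FALSE	TRUE	FALSE
Leptotrichia buccalis	species	supragingival	FL	ANCOM	patient	FALSE	TRUE	FALSE
Mogibacterium timidum	species	saliva	WGS	ANCOM	patient	FALSE	TRUE	FALSE
Mogibacterium timidum	species	saliva	FL	ANCOM	patient	FALSE	TRUE	FALSE
Mogibacterium timidum	species	saliva	SR	ANCOM	patient	FALSE	TRUE	TRUE
Mogibacterium timidum	species	supragingival	FL	ANCOM	patient	FALSE	TRUE	TRUE
Mogibacterium timidum	species	supragingival	SR	ANCOM	patient	FALSE	TRUE	FALSE
Olsenella uli	species	saliva	WGS	ANCOM	patient	TRUE	TRUE	FALSE
Olsenella uli	species	saliva	SR	ANCOM	patient	FALSE	TRUE	FALSE
Olsenella uli	species	supragingival	SR	ANCOM	patient	TRUE	FALSE	FALSE
Dialister invisus	species	saliva	WGS	ANCOM	patient	FALSE	TRUE	TRUE
Dialister invisus	species	saliva	FL	ANCOM	patient	FALSE	TRUE	FALSE
Dialister invisus	species	supragingival	FL	ANCOM	patient	TRUE	TRUE	FALSE
Dialister invisus	species	supragingival	SR	ANCOM	patient	FALSE	FALSE	FALSE
Schwartzia succinivorans	species	saliva	FL	ANCOM	patient	FALSE	TRUE	TRUE
Schwartzia succinivorans	species	saliva	SR	ANCOM	patient	TRUE	TRUE	TRUE
Schwartzia succinivorans	species	supragingival	FL	ANCOM	patient	TRUE	TRUE	TRUE
Schwartzia succinivorans	species	supragingival	SR	ANCOM	patient	TRUE	TRUE	TRUE
Streptococcus-anginosus-group-member	species	saliva	FL	ANCOM	patient	FALSE	TRUE	TRUE
Streptococcus-anginosus-group-member	species	saliva	SR	ANCOM	patient	FALSE	FALSE	TRUE
Streptococcus-anginosus-group-member	species	supragingival	FL	ANCOM	patient	FALSE	TRUE	FALSE
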