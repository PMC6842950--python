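# Synthetic stand-in for a curated antibiotic-related protein-name list
# (one name per line; matching is exact, case-insensitive,
# whitespace-normalized).  Assembled from widely reported resistance and
# biosynthesis protein names; replace with a project-specific curation
# for real analyses.
Chloramphenicol acetyltransferase (EC 2.3.1.28)
Transcriptional regulator, TetR family
Beta-lactamase
Penicillin-binding protein 1B (PBP-1b) (PBP1b) (Murein polymerase)
Penicillin-binding protein 2
Penicillin-binding protein
Glyoxalase/bleomycin resistance protein/dioxygenase
Macrolide export ATP-binding/permease protein MacB (EC 3.6.3.-)
Putative amidase
Penicillin amidase
Tetracycline resistance protein
Aminoglycoside N(3)-acetyltransferase
Vancomycin resistance protein VanA
Erythromycin esterase
Streptomycin 3''-adenylyltransferase
Multidrug resistance protein MdtA
Dihydropteroate synthase
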