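{
  "version": "1.1",
  "comment": "Amino-acid log-enrichment weights and per-position importance weights of the position-weighted T-cell immunogenicity model for 9-mer class I ligands (Calis et al. 2013, PLoS Comput Biol 9:e1003266), as distributed with the IEDB immunogenicity tool. Positions 1, 2 and the C-terminus are anchor positions and are masked by default when no HLA allele is specified.",
  "residue_log_enrichment": {
    "A": 0.127, "C": -0.175, "D": 0.072, "E": 0.325, "F": 0.38,
    "G": 0.11, "H": 0.105, "I": 0.432, "K": -0.7, "L": -0.036,
    "M": -0.57, "N": -0.021, "P": -0.036, "Q": -0.376, "R": 0.168,
    "S": -0.537, "T": 0.126, "V": 0.134, "W": 0.719, "Y": -0.012
  },
  "position_weights": [0.0, 0.0, 0.1, 0.31, 0.3, 0.29, 0.26, 0.18, 0.0],
  "masked_positions": [1, 2, 9]
}
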