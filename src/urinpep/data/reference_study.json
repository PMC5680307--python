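{
  "description": "Published per-protease regulated-peptide counts, activity scores and cross-omics direction calls from a urinary peptidomics study of diabetic nephropathy (121 macroalbuminuric cases vs 118 normoalbuminuric diabetic controls; 302 differentially abundant peptides; 30 predicted proteases with 135 protease-peptide associations).",
  "n_up": 93,
  "n_down": 42,
  "proteases": [
    {"protease": "CTSD",   "occ_down": 1,  "occ_up": 9, "pct_freq": 80,  "score": 9.65,   "transcriptomics": "increase",     "protein_expression": "increase"},
    {"protease": "KLK4",   "occ_down": 0,  "occ_up": 7, "pct_freq": 100, "score": 7.53,   "transcriptomics": "missing",      "protein_expression": "missing"},
    {"protease": "PCSK4",  "occ_down": 0,  "occ_up": 7, "pct_freq": 100, "score": 7.53,   "transcriptomics": "missing",      "protein_expression": "missing"},
    {"protease": "PCSK5",  "occ_down": 0,  "occ_up": 7, "pct_freq": 100, "score": 7.53,   "transcriptomics": "inconclusive", "protein_expression": "missing"},
    {"protease": "PCSK6",  "occ_down": 0,  "occ_up": 7, "pct_freq": 100, "score": 7.53,   "transcriptomics": "decrease",     "protein_expression": "missing"},
    {"protease": "PCSK7",  "occ_down": 0,  "occ_up": 7, "pct_freq": 100, "score": 7.53,   "transcriptomics": "inconclusive", "protein_expression": "missing"},
    {"protease": "MMP-7",  "occ_down": 0,  "occ_up": 5, "pct_freq": 100, "score": 5.38,   "transcriptomics": "increase",     "protein_expression": "increase"},
    {"protease": "CTSK",   "occ_down": 0,  "occ_up": 3, "pct_freq": 100, "score": 3.23,   "transcriptomics": "increase",     "protein_expression": "missing"},
    {"protease": "MMP-26", "occ_down": 0,  "occ_up": 3, "pct_freq": 100, "score": 3.23,   "transcriptomics": "decrease",     "protein_expression": "missing"},
    {"protease": "MMP-20", "occ_down": 2,  "occ_up": 3, "pct_freq": 20,  "score": 1.60,   "transcriptomics": "missing",      "protein_expression": "missing"},
    {"protease": "MMP-1",  "occ_down": 1,  "occ_up": 2, "pct_freq": 33,  "score": 1.51,   "transcriptomics": "increase",     "protein_expression": "missing"},
    {"protease": "MMP-13", "occ_down": 10, "occ_up": 4, "pct_freq": -43, "score": -12.05, "transcriptomics": "decrease",     "protein_expression": "no_change"},
    {"protease": "MMP-9",  "occ_down": 10, "occ_up": 6, "pct_freq": -25, "score": -7.57,  "transcriptomics": "missing",      "protein_expression": "decrease"},
    {"protease": "MMP-2",  "occ_down": 4,  "occ_up": 1, "pct_freq": -60, "score": -6.36,  "transcriptomics": "increase",     "protein_expression": "no_change"},
    {"protease": "MMP-3",  "occ_down": 4,  "occ_up": 1, "pct_freq": -60, "score": -6.36,  "transcriptomics": "increase",     "protein_expression": "increase"},
    {"protease": "MMP-8",  "occ_down": 5,  "occ_up": 2, "pct_freq": -43, "score": -6.02,  "transcriptomics": "decrease",     "protein_expression": "no_change"},
    {"protease": "MMP-12", "occ_down": 4,  "occ_up": 2, "pct_freq": -33, "score": -3.89,  "transcriptomics": "missing",      "protein_expression": "no_change"}
  ]
}
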