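"""Published benchmark of 12 solubility predictors on a balanced test set of
3100 sequences: (method, AUC, threshold, printed ACC %, printed MCC, TP, TN,
FP, FN). Shared by the evaluation and acceptance tests."""

BENCHMARK_TABLE = [
    ("SoluProt", 0.62, 0.50, 58.5, 0.17, 939, 873, 677, 611),
    ("PROSO II", 0.60, 0.60, 58.0, 0.17, 630, 1167, 383, 920),
    ("SWI", 0.60, 0.50, 55.9, 0.13, 1206, 527, 1023, 344),
    ("CamSol", 0.57, 1.00, 54.1, 0.08, 676, 1001, 549, 874),
    ("ESPRESSO", 0.56, 0.50, 53.8, 0.08, 1003, 664, 886, 547),
    ("rWH", 0.55, 0.50, 54.0, 0.08, 670, 1005, 545, 880),
    ("DeepSol", 0.55, 0.50, 52.9, 0.09, 230, 1409, 141, 1320),
    ("Protein-Sol", 0.54, 0.45, 51.6, 0.03, 1056, 544, 1006, 494),
    ("SOLpro", 0.53, 0.50, 52.0, 0.04, 654, 959, 591, 896),
    ("SKADE", 0.51, 0.50, 49.2, -0.03, 159, 1366, 184, 1391),
    ("ccSOL omics", 0.51, 0.50, 50.8, 0.02, 884, 690, 860, 666),
    ("RPSP", 0.50, 0.50, 49.8, 0.00, 501, 1044, 506, 1049),
]
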