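"""Score a predicted partition against ground truth with six validity indices.

RI/ARI/FMI compare partitions pair-by-pair, NMI/AMI share information-
theoretically, and ACC matches clusters to classes optimally (Hungarian
assignment).  All are invariant to relabeling; ARI and AMI are corrected
for chance so random partitions score near 0.
"""

from scfse.metrics import evaluate

truth = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]
pred = [1, 1, 1, 0, 0, 0, 0, 0, 2, 2, 2, 2]  # two cells misplaced

report = evaluate(truth, pred)
for key in ("ri", "ari", "nmi", "ami", "acc", "fmi"):
    print(f"{key:>4}: {report[key]:.4f}")
print(f"n={report['n']}  K_true={report['K_true']}  K_pred={report['K_pred']}")
# acc = 10/12 here: the optimal matching pairs each predicted cluster with
# one true class and two cells land in the wrong cluster.
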