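# demo pipeline configuration; paths are relative to the working directory
t0_path: features_t0.csv
t1_path: features_t1.csv
design_path: design.csv
out_dir: demo_run
stability_threshold: 0.95
# controls only: case nodules genuinely change between screens, and the
# all-subject filter would discard exactly the informative delta features
stability_on: train_controls
schemes: [three_class, two_class]
selectors: [relieff, cfs]
ks: [5, 10]
# the four fast classifiers keep the demo interactive; add svm_rbf/svm_linear
# for the full grid
classifiers: [decision_tree, rule_list, naive_bayes, random_forest]
smote_options: [false, true]
seed: 1
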