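from hypothesis import settings

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")

# Printed scheme means from the two long-term experiments, with the published
# load estimates they reproduce: (label, P_O, P_I, F_parents, F_offspring,
# published delta, published se).
PUBLISHED_LOADS = [
    ("madrid_base_112", 86.91, 70.30, 0.25, 0.25, 0.848, 0.142),
    ("madrid_base_201", 94.99, 90.60, 0.25, 0.375, 0.151, 0.070),
    ("madrid_base_234", 86.96, 83.11, 0.25, 0.375, 0.145, 0.098),
    ("madrid_lines_120", 81.84, 78.30, 0.25, 0.375, 0.141, 0.075),
    ("madrid_lines_153", 72.04, 71.72, 0.25, 0.375, 0.014, 0.083),
    ("vigo_base_22", 101.97, 47.56, 0.375, 0.5, 1.744, 0.112),
    ("vigo_base_50", 45.94, 29.71, 0.25, 0.375, 1.395, 0.136),
    ("vigo_base_103", 95.32, 71.24, 0.375, 0.5, 0.666, 0.188),
    ("vigo_base_111", 87.30, 72.16, 0.25, 0.375, 0.609, 0.109),
    ("vigo_base_125", 64.35, 62.08, 0.25, 0.375, 0.115, 0.069),
    ("vigo_lines_25", 89.49, 71.28, 0.25, 0.375, 0.728, 0.111),
    ("vigo_lines_39", 58.35, 59.19, 0.25, 0.375, -0.046, 0.063),
]
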