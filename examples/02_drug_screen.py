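"""Screen all nine drug mechanisms in the three hypercortisolism conditions.

Chronic stress: verdicts come from 200-day treatment simulations on the
adapted axis.  The Cushing conditions are judged on the analytic
clinical-branch steady states with a dose search.
"""

from hpaxis import run_screen

for condition in ("chronic_stress", "pituitary_adenoma", "adrenal_adenoma"):
    report = run_screen(condition)
    print(f"\n=== {condition} ===")
    print(report.frame()[["drug", "cortisol_fold", "net_gr_fold", "verdict"]]
          .to_string(index=False))
    print(f"effective: {len(report.effective)} / {len(report.rows)}")

# Only CRH-targeting mechanisms lower long-term cortisol under chronic
# stress (gland-mass compensation erases the rest); ACTH/cortisol-targeting
# drugs work in Cushing's disease, and only cortisol-targeting drugs in
# adrenal adenoma — three pairwise-different effective sets.
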