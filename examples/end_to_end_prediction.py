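"""Run the full seizure-prediction benchmark on a synthetic cohort.

Five subjects, two 22-minute sessions each (seizure onset at minute 20,
10-minute preictal state). Per subject, session 1 trains the CSP filter and
the SVM; session 2 is evaluated: CSP surrogate -> EMD denoising -> 7-moment
features -> window classification -> alarm after 3 consecutive preictal
windows. Takes a minute or two.
"""

from preictal import run_synthetic_experiment

result = run_synthetic_experiment(seed=1)
report = result.report

print(f"seizure sessions evaluated : {report.n_seizure_sessions}")
print(f"sensitivity                : {report.sensitivity_pct:.1f} % "
      "(seizures alarmed before onset)")
print(f"window specificity         : {report.specificity_pct:.2f} % "
      "(interictal windows kept quiet)")
print(f"avg anticipation           : {report.avg_anticipation_min:.2f} min")
print(f"max anticipation           : {report.max_anticipation_min:.2f} min")
print(f"false alarms               : {report.fpr_per_hour:.2f} per interictal hour")
print("\nper-session breakdown:")
for s in report.per_session:
    print(f"  {s['session_id']}: predicted={s.get('predicted')} "
          f"anticipation={s.get('anticipation_min')} min "
          f"tp/fp/tn/fn={s['tp']}/{s['fp']}/{s['tn']}/{s['fn']}")
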