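# Declarative analysis surface: which variable is summarized/tested how in the
# group-comparison table, and which correlation method pairs with the siMS
# score for each biomarker. Scales: mean_sd -> t test, median_iqr ->
# Mann-Whitney, proportion -> chi-square, distribution -> Fisher exact (2xk).
table1:
  - {variable: weight,               label: "Body weight (kg)",            scale: mean_sd,    test: t_test}
  - {variable: bmi,                  label: "BMI (kg/m2)",                 scale: mean_sd,    test: t_test}
  - {variable: obesity_label,        label: "Obese",                       scale: proportion, test: chi_square, level: obese}
  - {variable: waist,                label: "WC (cm)",                     scale: mean_sd,    test: t_test}
  - {variable: sbp,                  label: "SBP (mmHg)",                  scale: mean_sd,    test: t_test}
  - {variable: dbp,                  label: "DBP (mmHg)",                  scale: mean_sd,    test: t_test}
  - {variable: cholesterol,          label: "Cholesterol (mmol/L)",        scale: mean_sd,    test: t_test}
  - {variable: hdl,                  label: "HDL-chol. (mmol/L)",          scale: mean_sd,    test: t_test}
  - {variable: ldl,                  label: "LDL-chol. (mmol/L)",          scale: mean_sd,    test: t_test}
  - {variable: triglycerides,        label: "Triglycerides (mmol/L)",      scale: median_iqr, test: mann_whitney}
  - {variable: glucose_0,            label: "Glycaemia 0' (mmol/L)",       scale: mean_sd,    test: t_test}
  - {variable: glucose_30,           label: "Glycaemia 30' (mmol/L)",      scale: mean_sd,    test: t_test}
  - {variable: glucose_120,          label: "Glycaemia 120' (mmol/L)",     scale: mean_sd,    test: t_test}
  - {variable: insulin_0,            label: "Insulin 0' (mIU/L)",          scale: median_iqr, test: mann_whitney}
  - {variable: insulin_30,           label: "Insulin 30' (mIU/L)",         scale: median_iqr, test: mann_whitney}
  - {variable: insulin_120,          label: "Insulin 120' (mIU/L)",        scale: median_iqr, test: mann_whitney}
  - {variable: insulin_mean,         label: "Insulin average (mIU/L)",     scale: median_iqr, test: mann_whitney}
  - {variable: homa_ir,              label: "HOMA IR",                     scale: median_iqr, test: mann_whitney}
  - {variable: hba1c,                label: "HbA1c (%)",                   scale: mean_sd,    test: t_test}
  - {variable: glyco_label,          label: "Glycoregulation impairment",  scale: distribution, test: fisher_exact}
  - {variable: crp,                  label: "CRP (mg/L)",                  scale: median_iqr, test: mann_whitney}
  - {variable: urea,                 label: "Urea (mmol/L)",               scale: mean_sd,    test: t_test}
  - {variable: creatinine,           label: "Creatinine (umol/L)",         scale: mean_sd,    test: t_test}
  - {variable: creatinine_clearance, label: "Creatinine clearance (mL/min)", scale: mean_sd,  test: t_test}
  - {variable: microalbuminuria,     label: "Microalbuminuria (mg/24h)",   scale: median_iqr, test: mann_whitney}
  - {variable: alt,                  label: "ALT (U/L)",                   scale: median_iqr, test: mann_whitney}
  - {variable: ast,                  label: "AST (U/L)",                   scale: median_iqr, test: mann_whitney}
  - {variable: ggt,                  label: "Gamma-GT (U/L)",              scale: median_iqr, test: mann_whitney}
  - {variable: fli,                  label: "Fatty liver index",           scale: median_iqr, test: mann_whitney}
  - {variable: uric_acid,            label: "Uric acid (umol/L)",          scale: mean_sd,    test: t_test}
  - {variable: homocysteine,         label: "Homocysteine (umol/L)",       scale: mean_sd,    test: t_test}
  - {variable: pai1,                 label: "PAI-1 (U/mL)",                scale: mean_sd,    test: t_test}
  - {variable: sims,                 label: "siMS score",                  scale: mean_sd,    test: t_test}

# siMS correlation screen: Pearson for approximately normal variables,
# Spearman for the skewed ones (and their raw forms); log-transformed
# variants are Pearson.
correlations:
  - {variable: weight,               method: pearson}
  - {variable: bmi,                  method: pearson}
  - {variable: waist,                method: pearson}
  - {variable: sbp,                  method: pearson}
  - {variable: dbp,                  method: pearson}
  - {variable: cholesterol,          method: pearson}
  - {variable: hdl,                  method: pearson}
  - {variable: ldl,                  method: pearson}
  - {variable: triglycerides,        method: spearman}
  - {variable: glucose_0,            method: pearson}
  - {variable: glucose_120,          method: pearson}
  - {variable: insulin_0,            method: spearman}
  - {variable: insulin_mean,         method: spearman}
  - {variable: homa_ir,              method: spearman}
  - {variable: log_homa_ir,          method: pearson}
  - {variable: hba1c,                method: pearson}
  - {variable: crp,                  method: spearman}
  - {variable: log_crp,              method: pearson}
  - {variable: urea,                 method: pearson}
  - {variable: creatinine,           method: pearson}
  - {variable: creatinine_clearance, method: pearson}
  - {variable: microalbuminuria,     method: spearman}
  - {variable: alt,                  method: spearman}
  - {variable: log_alt,              method: pearson}
  - {variable: ast,                  method: spearman}
  - {variable: ggt,                  method: spearman}
  - {variable: log_ggt,              method: pearson}
  - {variable: fli,                  method: spearman}
  - {variable: log_fli,              method: pearson}
  - {variable: uric_acid,            method: pearson}
  - {variable: homocysteine,         method: pearson}
  - {variable: pai1,                 method: pearson}
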