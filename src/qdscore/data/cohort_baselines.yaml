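# Cohort-shaped generator defaults: per-indicator pre-treatment mean/SD and
# post-treatment mean/SD on the natural scale, for a 15-patient artificial-
# liver-support (dpmas) arm and a 12-patient conventional-treatment arm of an
# ACLF study.  The generator draws pre-treatment values from a log-normal
# moment-matched to (pre_mean, pre_sd); the built-in effect profiles use
# post_mean / pre_mean as the expected post/pre multiplier.

arms:
  dpmas:
    n: 15
    indicators:
      hemoglobin:                 {pre_mean: 112.47,  pre_sd: 22.42,   post_mean: 89.53,   post_sd: 23.11}
      white_blood_cell:           {pre_mean: 9.29,    pre_sd: 4.99,    post_mean: 11.22,   post_sd: 5.82}
      red_blood_cell:             {pre_mean: 3.98,    pre_sd: 1.75,    post_mean: 2.66,    post_sd: 0.77}
      platelet:                   {pre_mean: 102.49,  pre_sd: 66.87,   post_mean: 106.27,  post_sd: 67.23}
      thrombocytocrit:            {pre_mean: 0.13,    pre_sd: 0.06,    post_mean: 0.15,    post_sd: 0.08}
      activated_partial_thromboplastin_time: {pre_mean: 53.44, pre_sd: 10.79, post_mean: 63.41, post_sd: 37.08}
      prothrombin_time:           {pre_mean: 23.71,   pre_sd: 7.09,    post_mean: 25.63,   post_sd: 13.09}
      thrombin_time:              {pre_mean: 33.51,   pre_sd: 33.21,   post_mean: 22.25,   post_sd: 7.1}
      fibrinogen:                 {pre_mean: 1.32,    pre_sd: 0.5,     post_mean: 1.40,    post_sd: 0.67}
      international_normalized_ratio: {pre_mean: 3.21, pre_sd: 4.44,   post_mean: 2.33,    post_sd: 1.32}
      uric_acid:                  {pre_mean: 228.38,  pre_sd: 140.69,  post_mean: 239.09,  post_sd: 127.74}
      creatinine:                 {pre_mean: 109.40,  pre_sd: 69.88,   post_mean: 109.78,  post_sd: 75.06}
      urea:                       {pre_mean: 8.10,    pre_sd: 8.8,     post_mean: 9.75,    post_sd: 8.51}
      glucose:                    {pre_mean: 8.47,    pre_sd: 3.63,    post_mean: 6.41,    post_sd: 3.17}
      alanine_aminotransferase:   {pre_mean: 689.29,  pre_sd: 966.99,  post_mean: 50.58,   post_sd: 26.83}
      aspartate_aminotransferase: {pre_mean: 593.71,  pre_sd: 536.28,  post_mean: 76.61,   post_sd: 29.5}
      total_bilirubin:            {pre_mean: 375.23,  pre_sd: 193.41,  post_mean: 220.75,  post_sd: 152.33}
      conjugated_bilirubin:       {pre_mean: 245.40,  pre_sd: 146.5,   post_mean: 105.27,  post_sd: 68.85}
      unconjugated_bilirubin:     {pre_mean: 120.25,  pre_sd: 94.92,   post_mean: 104.04,  post_sd: 97.16}
      cholinesterase:             {pre_mean: 3736.25, pre_sd: 1493.02, post_mean: 3027.83, post_sd: 771.09}
      gamma_glutamyl_transferase: {pre_mean: 192.02,  pre_sd: 224.2,   post_mean: 105.41,  post_sd: 122.09}
  conventional:
    n: 12
    indicators:
      hemoglobin:                 {pre_mean: 115.42,  pre_sd: 31.44,   post_mean: 102.91,  post_sd: 28.49}
      white_blood_cell:           {pre_mean: 9.03,    pre_sd: 6.06,    post_mean: 8.33,    post_sd: 3.72}
      red_blood_cell:             {pre_mean: 4.19,    pre_sd: 1.49,    post_mean: 3.38,    post_sd: 1.12}
      platelet:                   {pre_mean: 111.42,  pre_sd: 80.54,   post_mean: 124.33,  post_sd: 92.42}
      thrombocytocrit:            {pre_mean: 0.18,    pre_sd: 0.11,    post_mean: 0.17,    post_sd: 0.09}
      activated_partial_thromboplastin_time: {pre_mean: 42.87, pre_sd: 11.57, post_mean: 48.39, post_sd: 11.67}
      prothrombin_time:           {pre_mean: 18.83,   pre_sd: 4.74,    post_mean: 21.14,   post_sd: 8.5}
      thrombin_time:              {pre_mean: 21.56,   pre_sd: 3.53,    post_mean: 25.20,   post_sd: 10}
      fibrinogen:                 {pre_mean: 2.16,    pre_sd: 1.45,    post_mean: 1.73,    post_sd: 0.73}
      international_normalized_ratio: {pre_mean: 1.64, pre_sd: 0.43,   post_mean: 1.85,    post_sd: 0.79}
      uric_acid:                  {pre_mean: 354.37,  pre_sd: 143.16,  post_mean: 271.76,  post_sd: 143.86}
      creatinine:                 {pre_mean: 131.90,  pre_sd: 109.8,   post_mean: 152.6,   post_sd: 138.22}
      urea:                       {pre_mean: 8.83,    pre_sd: 10.98,   post_mean: 11.27,   post_sd: 9.87}
      glucose:                    {pre_mean: 6.87,    pre_sd: 1.73,    post_mean: 5.84,    post_sd: 1.85}
      alanine_aminotransferase:   {pre_mean: 601.21,  pre_sd: 1109.7,  post_mean: 247.04,  post_sd: 589.4}
      aspartate_aminotransferase: {pre_mean: 419.21,  pre_sd: 570.33,  post_mean: 310.00,  post_sd: 525.12}
      total_bilirubin:            {pre_mean: 205.73,  pre_sd: 166.14,  post_mean: 268.68,  post_sd: 221.29}
      conjugated_bilirubin:       {pre_mean: 136.83,  pre_sd: 134.83,  post_mean: 174.74,  post_sd: 163.26}
      unconjugated_bilirubin:     {pre_mean: 67.41,   pre_sd: 55.92,   post_mean: 89.22,   post_sd: 99.74}
      cholinesterase:             {pre_mean: 4107.52, pre_sd: 2203.11, post_mean: 3282.87, post_sd: 1256.68}
      gamma_glutamyl_transferase: {pre_mean: 341.4,   pre_sd: 324.48,  post_mean: 208.43,  post_sd: 193.01}
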