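# Feature dictionary

The canonical 25 columns produced by `fruitvol.features.build_feature_vector`
and `featurize_table` (in order), with units. Semi-axes: `a = w_top/2`,
`b = h_top/2`, `c_sw = w_side/2`, `c_sh = h_side/2`, `c_avg = (w_side+h_side)/4`.

| # | column | unit | definition |
|---|--------|------|------------|
| 1 | `w_top` | mm | top-view silhouette width |
| 2 | `h_top` | mm | top-view silhouette height |
| 3 | `w_side` | mm | side-view silhouette width |
| 4 | `h_side` | mm | side-view silhouette height |
| 5 | `mean_diameter` | mm | mean of the four dimensions |
| 6 | `v_ellip_avg` | mL | (4/3) pi a b c_avg / 1000 |
| 7 | `v_ellip_sw` | mL | (4/3) pi a b c_sw / 1000 |
| 8 | `v_ellip_sh` | mL | (4/3) pi a b c_sh / 1000 |
| 9 | `v_sphere` | mL | (4/3) pi (mean_diameter/2)^3 / 1000 |
| 10 | `area_top` | mm^2 | pi a b |
| 11 | `area_side` | mm^2 | pi c_sw c_sh |
| 12 | `perimeter_top` | mm | Ramanujan perimeter of ellipse (a, b) |
| 13 | `perimeter_side` | mm | Ramanujan perimeter of ellipse (c_sw, c_sh) |
| 14 | `surface_area` | mm^2 | Knud-Thomsen surface of ellipsoid (a, b, c_avg), p = 1.6075 |
| 15 | `sphericity` | — | pi^(1/3) (6 V_ellip_avg·1000)^(2/3) / surface_area |
| 16 | `sa_to_vol` | mm^2/mL | surface_area / v_ellip_avg |
| 17 | `aspect_top` | — | w_top / h_top |
| 18 | `aspect_side` | — | w_side / h_side |
| 19 | `ratio_w_top_w_side` | — | w_top / w_side |
| 20 | `ratio_h_top_h_side` | — | h_top / h_side |
| 21 | `ratio_area_top_side` | — | area_top / area_side |
| 22 | `ecc_top` | — | sqrt(1 − (min(a,b)/max(a,b))^2) |
| 23 | `ecc_side` | — | sqrt(1 − (min(c_sw,c_sh)/max(c_sw,c_sh))^2) |
| 24 | `inter_area_top_w_side` | mm^3 | area_top × w_side |
| 25 | `inter_area_side_h_top` | mm^3 | area_side × h_top |

Columns 1–14 and 24–25 are strictly positive and are log-transformed
during preprocessing; columns 15–23 stay on their natural scale.
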