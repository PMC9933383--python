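term_id,label,kind,uberon,fma,cl
anal_canal,anal canal,region,UBERON:0000159,FMA:15703,
rectum,rectum,region,UBERON:0001052,FMA:14544,
sigmoid_colon,sigmoid colon,region,UBERON:0001159,FMA:14548,
descending_colon,descending colon,region,UBERON:0001158,FMA:14547,
transverse_colon,transverse colon,region,UBERON:0001157,FMA:14546,
ascending_colon,ascending colon,region,UBERON:0001156,FMA:14545,
caecum,caecum,region,UBERON:0001153,FMA:14541,
appendix,vermiform appendix,region,UBERON:0001154,FMA:14542,
ileum,ileum,region,UBERON:0002116,FMA:7208,
jejunum,jejunum,region,UBERON:0002115,FMA:7207,
duodenum,duodenum,region,UBERON:0002114,FMA:7206,
anus,anus,landmark,UBERON:0001245,FMA:15711,
ileocaecal_valve,ileocaecal valve,landmark,UBERON:0000569,FMA:15973,
hepatic_flexure,hepatic flexure,landmark,UBERON:0022277,FMA:14550,
splenic_flexure,splenic flexure,landmark,UBERON:0022276,FMA:14551,
anterior_peritoneal_reflection,anterior peritoneal reflection,landmark,,,
mucosa,mucosa,wall_layer,UBERON:0000344,FMA:85355,
submucosa,submucosa,wall_layer,UBERON:0000009,FMA:85356,
muscularis_propria,muscularis propria,wall_layer,UBERON:0006660,FMA:85357,
serosa,serosa,wall_layer,UBERON:0000042,FMA:85358,
goblet_cell,goblet cell,cell_type,,,CL:0000160
enterocyte,enterocyte,cell_type,,,CL:0000584
paneth_cell,Paneth cell,cell_type,,,CL:0000510
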