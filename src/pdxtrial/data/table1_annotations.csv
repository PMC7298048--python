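tumor_id,site,patient_histology,patient_er,patient_her2,patient_subtype,gbrca,prior_therapy,aln,distant,pdx_id,pdx_histology,pdx_er,pdx_her2,pdx_subtype
GCRC1715T,Breast,IDC-NOS,1%,-,HER2E,,"A, C, T",+,-,GCRC1715X,IDC-NOS,-,-,HER2E
GCRC1735T,Breast,IDC-NOS,-,FISH 2.2,Basal,BRCA1,"A, C, T, H",-,-,GCRC1735X,IDC-NOS,-,FISH 2.2,Basal
GCRC1738T,Breast,IDC-NOS,-,-,Basal,BRCA1 benign,"A, C, T",-,+,GCRC1738X,IDC-NOS,-,-,Basal
GCRC1784T,Breast,MBC (chondroid),15%,-,Basal,,"A, C, T",+,+,GCRC1784Xd,IDC-NOS,-,-,Basal
GCRC1784T,Breast,MBC (chondroid),15%,-,Basal,,"A, C, T",+,+,GCRC1784Xc,MBC (chondroid),-,-,Basal
GCRC2054T,MLN,Met Ca (1° MBC chondroid),-,-,N/A,,"A*, C*, T*, M*, F*",+,+,GCRC2054X,IDC-NOS,-,-,Basal
GCRC1828T,Breast,ACC,-,-,Normal,,None,-,-,GCRC1828X,ACC,-,-,Basal
GCRC1834T,Breast,IDC-NOS,-,-,Basal,,None,+,+,GCRC1834X,IDC-NOS,-,-,Basal
GCRC1840T,Breast,IDC-NOS,-,-,Basal,,None,+,-,GCRC1840X,IDC-NOS,-,-,Basal
GCRC1851T,Breast,IDC-NOS,-,-,Basal,BRCA1,None,-,-,GCRC1851X,IDC-NOS,-,-,Basal
GCRC1856T,Brain,Met Ca (1° IDC-NOS),-,+,HER2E,,"H, V",-,+,GCRC1856X,IDC-NOS,-,+,HER2E
GCRC1863T,Breast,IDC in MGA,-,-,Basal,,"E, C, T",-,-,GCRC1863X,IDC-NOS,-,-,Basal
GCRC1868T,Breast,IDC-NOS,10%,-,Basal,,"T, nab-T",+,-,GCRC1868X,IDC-NOS,10%,-,Basal
GCRC1876T,Breast,IDC-NOS,-,-,Basal,,None,-,-,GCRC1876X,IDC-NOS,-,-,Basal
GCRC1882T,Breast,IDC-NOS,5%,-,Basal,,L,-,-,GCRC1882X,IDC-NOS,-,-,Basal
GCRC1886T,Breast,IDC (pleomorphic),-,-,Normal,,"A, C, Car, T",-,-,GCRC1886X,IDC-NOS,-,-,Basal
GCRC1887T,Brain,Met Ca (1° MBC squamous),+,-,HER2E,BRCA2,"A*, C, T*, L*, Ex*, Cap*, V*, D, Car",+,+,GCRC1887X,MBC (squamous),+,-,HER2E
GCRC1905T,Breast,IDC-NOS,-,-,Basal,,None,-,-,GCRC1905X,IDC-NOS,-,-,Basal
GCRC1915T,Breast,IDC-NOS,-,-,Basal,,"A, C, Car, T",-,+,GCRC1915X,IDC-NOS,-,-,Basal
GCRC2076T,Lung,Met Ca (1° IDC-NOS),-,-,N/A,,"A*, C*, T*, Car*, M*, F*",-,+,GCRC2076X,IDC-NOS,-,-,Basal
GCRC1924T,ALN,Met Ca (1° IDC-NOS),-,-,N/A,BRCA1 VUS,"D, C",+,-,GCRC1924X,IDC-NOS,-,-,Basal
GCRC1939T,Breast,IDC-NOS,-,-,Basal,,"A, C, T, D",+,+,GCRC1939X,IDC-NOS,-,-,Basal
GCRC1944T,Brain,Met Ca (1° IDC-NOS),- (1° +),+,N/A,,"T*, Car*, H*, A*, C*, V*, Cap*, T-DM1, Tam",+,+,GCRC1944X,IDC-NOS,+,+,HER2E
GCRC1945T,Brain,Met Ca (1° IDC-NOS),-,-,Basal,,"A*, C*, D*, T, Car, Cap*",+,+,GCRC1945X,IDC-NOS,-,-,Basal
GCRC1963T,Breast,IDC-NOS,-,-,Basal,BRCA1,None,-,-,GCRC1963X,IDC-NOS,-,-,Basal
GCRC1971T,Skin,Met Ca (1° ILC),- (1° +),-,HER2E,,"L, D*, C*, Fulv, Tas",+,+,GCRC1971X,ILC,+,-,HER2E
GCRC1979T,2° Breast,NE,-,-,N/A,,"E, C, T",+,+,GCRC1979X,NE,-,-,HER2E
GCRC1986T,Liver,Met Ca (1° IDC-NOS),+,-,N/A,,"A, C, T, Cis, C, F",+,+,GCRC1986X,IDC-NOS,+,-,Basal
GCRC1991T,Breast,IDC-NOS,-,+,HER2E,,"A*, C*, T, H, V, T-DM1, ONT-380",-,+,GCRC1991X,IDC-NOS,-,+,HER2E
GCRC2001T,Breast,IDC-NOS,1%,-,Basal,,None,-,-,GCRC2001X,IDC-NOS,-,-,HER2E
GCRC2006T,Breast,IDC-NOS,-,-,Basal,BRCA1,None,+,-,GCRC2006X,IDC-NOS,-,-,Basal
GCRC2007T,2° Breast,Mucinous,+,-,LumB,,None,-,-,GCRC2007X,Mucinous,+,-,LumB
GCRC2029T,Breast,MBC (squamous),-,-,Basal,,"A, C, T, Cis",+,-,GCRC2029X,MBC (squamous),-,-,HER2E
GCRC2047T,Breast,IDC-NOS,1%,-,Basal,,"A, C, T",+,-,GCRC2047X,IDC-NOS,-,-,Basal
GCRC2061T,Breast,IDC-NOS,-,-,Basal,BRCA1,None,+,-,GCRC2061X,IDC-NOS,-,-,Basal
GCRC2080T,Breast,IDC-NOS,-,+,HER2E,,"A, C, T, V, H, Cis",+,+,GCRC2080X,IDC-NOS,-,+,HER2E
GCRC2089T,Breast,IDC-NOS,-,-,N/A,,"A, C, Car, T",-,-,GCRC2089X,IDC-NOS,-,-,Basal
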