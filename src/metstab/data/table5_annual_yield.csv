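genotype,mws_tdw,mws_tdw_letters,mws_cpy,mws_cpy_letters,sws_tdw,sws_tdw_letters,sws_cpy,sws_cpy_letters,top_cpy_mws,top_cpy_sws
1026,18.9,p,1281.06,l,17.99,b,1448.47,hi,False,False
16816,22.8,lmn,1570.71,hi,22.05,yza,1863.46,abcdef,False,False
14355,48.48,ij,3240.65,ghij,48.21,fg,3648.34,efg,True,True
16817,35.68,tuvw,2300.43,uvw,34.07,opq,2456.48,rst,False,False
14389,29.28,cdefg,2154.83,wxy,27.75,uv,2172.14,uvwxy,False,False
16818,25.47,ijk,1640.72,ghi,25.13,wx,1931.0,zabcd,False,False
14982,31.91,yzab,2375.85,stu,30.83,rst,2343.17,stu,False,False
16819,63.57,b,3893.9,c,62.43,b,4430.8,b,True,True
14983,43.95,k,3423.47,ef,43.31,h,3862.63,de,False,False
16821,24.41,klm,1613.06,ghi,23.56,xy,1719.4,efg,False,False
14984,41.02,lmno,2663.53,p,39.33,jk,2877.39,lm,False,False
16822,29.58,bcdefg,1901.39,bcd,29.1,tuv,1907.54,abcde,False,False
15357,49.97,hi,3342.45,efgh,47.66,fg,3572.8,fg,True,True
16834,15.26,q,1111.38,m,14.43,c,1177.9,j,False,False
16621,2.9,t,164.84,p,2.66,f,201.87,lm,False,False
16835,19.25,p,1377.79,kl,18.14,b,1413.72,i,False,False
16782,31.53,yzabc,2139.68,wxyz,31.71,pqrs,2080.56,vwxyza,False,False
16836,21.56,no,1525.72,ij,20.33,a,1778.28,cdef,False,False
16783,40.43,mno,2511.52,qrs,38.16,kl,2647.38,nopqr,False,False
16837,27.5,ghi,1835.66,cde,24.92,x,1908.07,abcde,False,False
16784,32.75,xyza,2369.07,tu,32.33,pqr,2691.07,nopq,False,False
16838,19.35,op,1372.03,kl,19.98,ab,1320.31,ij,False,False
16785,27.76,efghi,1515.86,ijk,27.47,vw,1808.73,bcdef,False,False
16839,48.09,ij,3199.29,hijk,46.91,fg,3567.88,fgh,True,True
16786,33.3,wxyz,2025.89,yzab,31.6,rs,2260.51,tuvw,False,False
16840,30.84,zabcd,2036.14,yzab,28.66,tuv,2081.19,vwxyza,False,False
16787,23.34,klmn,1522.19,ij,21.21,za,1668.73,fgh,False,False
16902,23.33,klmn,1578.78,hi,21.98,yza,1739.71,defg,False,False
16788,29.66,bcdef,1978.48,zab,27.61,uv,2080.21,vwxyza,False,False
18438,42.39,klmn,2958.7,no,40.76,ij,3718.42,ef,True,False
16789,38.09,pqrs,2313.41,uv,36.9,lmn,2619.82,opqr,False,False
18448,40.05,nop,2966.61,no,38.12,kl,3115.94,jk,True,False
16790,11.64,r,813.97,n,10.45,d,790.64,k,False,False
18662,2.65,t,151.77,p,2.47,f,139.56,m,False,False
16791,68.05,a,4429.1,a,67.35,a,5213.84,a,True,True
15743,39.93,nop,2530.31,pqrs,37.49,klmn,2501.03,qrs,False,False
16792,39.54,op,2200.51,vwx,38.41,kl,2494.38,rs,False,False
BAGCE 100,54.21,ef,3101.07,jklmn,55.11,d,3684.03,ef,True,True
16793,25.56,ijk,1585.26,ghi,23.86,xy,1669.11,fgh,False,False
BAGCE 17,37.38,qrst,3016.64,lmn,37.57,klm,3215.17,ijk,True,False
16794,33.46,wxy,2333.49,tuv,31.63,qrs,2705.3,mnopq,False,False
BAGCE 30,59.94,c,4130.07,b,58.37,c,4466.59,b,True,True
16795,42.0,klmn,2632.63,pq,40.48,ij,2828.19,lmn,False,False
BAGCE 34,52.51,fg,3145.92,ijklm,51.03,e,3750.61,def,True,True
16796,21.16,nop,1393.36,jkl,19.71,ab,1534.64,ghi,False,False
BAGCE 53,42.74,klm,2976.08,no,41.28,hij,3348.2,hij,True,False
16797,6.28,s,464.86,o,6.11,e,421.85,l,False,False
BAGCE 81,39.02,opqr,2943.12,no,37.75,kl,3163.11,jk,True,False
16798,31.89,yzab,1966.69,abc,31.62,qrs,2247.3,tuvw,False,False
BAGCE 86,36.58,rstu,2600.97,pqr,35.22,mno,2518.56,pqrs,False,False
16799,25.1,jkl,1693.38,fgh,23.87,xy,1737.6,defg,False,False
BAGCE 93,52.27,fg,3818.98,cd,50.94,e,4469.65,b,True,True
16800,33.72,vwxy,2024.91,yzab,31.95,pqrs,2180.03,uvwxy,False,False
BAGCE 97,43.35,k,3256.66,ghij,42.43,hi,3631.1,efg,True,False
16801,30.26,bcd,1829.93,cdef,28.89,tuv,1987.33,xyzabc,False,False
CNPGL 00-1-1,48.86,ij,3697.89,d,45.97,g,3520.77,fgh,True,True
16802,55.11,de,3342.67,efgh,55.47,d,3966.85,cd,True,True
CNPGL 92-133-3,30.88,zabcd,2165.94,wxy,30.88,rst,2711.36,mnopq,False,False
16803,30.69,abcd,2028.23,yzab,27.25,vw,1918.03,zabcde,False,False
CNPGL 92-198-7,51.64,gh,3381.83,efg,49.35,ef,4169.44,c,True,True
16804,30.09,bcdef,2202.14,vwx,27.73,uv,2219.09,uvwx,False,False
CNPGL 92-56-2,47.63,j,3156.48,ijkl,46.1,g,3541.91,fgh,True,True
16805,5.1,s,400.24,o,4.79,e,297.49,lm,False,False
CNPGL 92-66-3,48.33,ij,3053.45,klmn,47.38,fg,3422.05,ghi,True,True
16806,30.59,bcd,2017.28,yzab,28.36,uv,1957.29,yzabcd,False,False
CNPGL 9279-2,34.22,vwx,2208.15,vwx,31.57,rs,2260.57,tuv,False,False
16807,43.0,kl,3297.35,fghi,42.26,hi,3201.01,ijk,False,False
CNPGL 93 -37-5,56.71,d,3479.82,e,55.75,d,3967.35,cd,True,True
16808,29.74,bcdef,2008.26,yzab,28.74,tuv,2152.11,uvwxyz,False,False
CNPGL 93-01-1,27.66,fghi,2138.5,xyz,24.67,x,2030.17,wxyzab,False,False
16809,33.84,vwxy,2370.2,stu,30.95,rst,2113.2,uvwxyz,False,False
CNPGL 93-04-2,39.51,opq,2952.96,no,39.58,jk,3160.9,jk,True,False
16810,21.61,no,1582.54,ghi,21.09,za,1494.81,hi,False,False
CNPGL 93-18-2,26.6,hij,2022.46,yzab,24.62,x,1831.22,bcdef,False,False
16811,41.69,klmn,3331.09,efgh,39.15,jk,3270.85,ij,True,False
CNPGL 94-13-1,38.99,opqr,2993.54,mn,38.05,kl,2735.53,mnop,False,False
16812,30.21,bcde,2467.96,rst,29.99,stu,2514.4,pqrs,False,False
CNPGL 96-21-1,28.93,defgh,2094.59,xyza,28.57,tuv,2251.7,tuvw,False,False
16813,22.46,mn,1741.49,defg,22.98,xyz,1865.04,abcdef,False,False
CNPGL 96-23-1,23.5,klmn,1698.31,efgh,23.03,xyz,1780.96,cdef,False,False
16814,42.99,kl,2600.77,pqr,42.19,hi,2983.3,kl,False,False
CNPGL 96-27-3,34.53,uvwx,2374.71,stu,33.08,opqr,2345.12,stu,False,False
16815,36.1,stuv,2825.58,o,35.05,no,3024.79,kl,False,False
Pioneiro,35.18,tuvw,2558.97,pqr,34.15,op,2797.11,lmno,False,False
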