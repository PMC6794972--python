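paste,condition,day,mean,sd,n,letter
EB@TiO2,WS,1,19.0,2.6,7,a
EB@TiO2,WS,2,35.1,4.4,7,a
EB@TiO2,WS,3,50.4,4.3,7,a
EB@TiO2,WS,4,62.0,3.7,7,a
EB@TiO2,WS,5,93.3,2.3,7,a
EB@TiO2,WS,6,95.1,1.6,7,a
EB@TiO2,WS,7,97.9,1.3,7,a
EB@TiO2,S,1,15.6,2.2,7,b
EB@TiO2,S,2,43.6,4.7,7,b
EB@TiO2,S,3,71.4,2.8,7,b
EB@TiO2,S,4,82.0,3.1,7,b
EB@TiO2,S,5,93.9,3.0,7,a
EB@TiO2,S,6,98.4,1.9,7,b
EB@TiO2,S,7,99.3,1.0,7,b
Colgate Pro-relief,WS,1,32.3,3.0,7,a
Colgate Pro-relief,WS,2,45.7,6.8,7,a
Colgate Pro-relief,WS,3,62.3,6.7,7,a
Colgate Pro-relief,WS,4,62.0,6.7,7,a
Colgate Pro-relief,WS,5,68.6,6.1,7,a
Colgate Pro-relief,WS,6,74.3,6.8,7,a
Colgate Pro-relief,WS,7,88.9,3.2,7,a
Colgate Pro-relief,S,1,16.0,3.6,7,b
Colgate Pro-relief,S,2,21.4,2.2,7,b
Colgate Pro-relief,S,3,20.3,2.7,7,b
Colgate Pro-relief,S,4,20.9,2.9,7,b
Colgate Pro-relief,S,5,19.9,3.4,7,b
Colgate Pro-relief,S,6,61.9,4.8,7,b
Colgate Pro-relief,S,7,80.1,8.6,7,b
Sensodyne repair,WS,1,12.9,3.6,7,a
Sensodyne repair,WS,2,13.6,2.5,7,a
Sensodyne repair,WS,3,13.4,2.8,7,a
Sensodyne repair,WS,4,15.0,3.3,7,a
Sensodyne repair,WS,5,16.0,3.1,7,a
Sensodyne repair,WS,6,17.0,3.7,7,a
Sensodyne repair,WS,7,70.1,4.2,7,a
Sensodyne repair,S,1,19.3,3.5,7,b
Sensodyne repair,S,2,29.0,2.2,7,b
Sensodyne repair,S,3,44.1,4.9,7,b
Sensodyne repair,S,4,60.9,4.6,7,b
Sensodyne repair,S,5,55.3,5.3,7,b
Sensodyne repair,S,6,53.3,6.2,7,b
Sensodyne repair,S,7,90.4,3.0,7,b
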